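"""Expression-matrix processing and paralog expression divergence.

Operations: probe-to-gene collapse (median across probe sets), gene-wise
z-normalization, hierarchical clustering on 1 - Pearson r with average
linkage, per-gene highest-tissue calls, binary expressed-tissue sets, the
four paralog divergence categories (disjoint / identical / subset / partial
overlap), and reference-gene-relative RT-qPCR quantification (2^-dCt).

"Expressed" means the gene-wise normalized value exceeds tau (default 0,
i.e. above the gene's own mean across samples); the threshold is a package
convention and is configurable everywhere it is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

#: the six developmental tissues profiled for the family
DEFAULT_TISSUES = ("Rt", "ML", "YL", "FC", "MC", "XL")

CATEGORY_NAMES = {
    1: "non-overlapping",
    2: "identical",
    3: "subset",
    4: "partial-overlap",
}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with unique sample labels."""

    df: pd.DataFrame  # index: gene ids, columns: sample labels

    def __post_init__(self) -> None:
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate sample labels")
        if self.df.isna().any().any():
            n = int(self.df.isna().any(axis=1).sum())
            logger.warning("dropping %d rows with missing values", n)
            self.df = self.df.dropna(axis=0)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_labels(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_map: pd.DataFrame
) -> ExpressionMatrix:
    """Collapse probe-level rows to gene rows, median across a gene's probes.

    Genes sharing one probe set receive identical rows (same transcriptional
    profile); probes absent from the map are dropped with a warning.
    """
    mapped = probe_map[probe_map["probe_id"].isin(probe_matrix.index)]
    unmapped = set(probe_matrix.index) - set(probe_map["probe_id"])
    if unmapped:
        logger.warning("dropping %d unmapped probes", len(unmapped))
    rows = {}
    for gene, grp in mapped.groupby("gene_id"):
        sub = probe_matrix.loc[grp["probe_id"]]
        rows[gene] = sub.median(axis=0)
    if not rows:
        raise ValueError("no probes could be mapped to genes")
    return ExpressionMatrix(pd.DataFrame(rows).T)


def genewise_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-row z-score: (x - row mean) / row SD, sample SD (ddof = 1).

    Rows with zero SD become all-zeros with a log entry; a single-sample
    matrix is an error.
    """
    if matrix.df.shape[1] < 2:
        raise ValueError("need >= 2 samples to normalize")
    values = matrix.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sd == 0).ravel()
    if degenerate.any():
        logger.warning(
            "%d constant rows set to zero: %s",
            int(degenerate.sum()),
            [g for g, d in zip(matrix.gene_ids, degenerate) if d][:10],
        )
    sd[sd == 0] = 1.0
    out = (values - mean) / sd
    out[degenerate, :] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.df.index, columns=matrix.df.columns)
    )


def cluster_genes(matrix: ExpressionMatrix) -> tuple[list, np.ndarray]:
    """Average-linkage agglomerative clustering on d = 1 - Pearson r.

    Returns (merge list, scipy linkage matrix); each merge entry is
    (cluster_i, cluster_j, height) with original rows numbered 0..n-1 and
    new clusters n, n+1, ... in merge order. Degenerate (zero-variance) rows
    are excluded with a warning before clustering.
    """
    values = matrix.values
    keep = values.std(axis=1, ddof=1) > 0
    if not keep.all():
        logger.warning("excluding %d degenerate rows", int((~keep).sum()))
        values = values[keep]
    if values.shape[0] < 2:
        raise ValueError("need >= 2 non-degenerate genes to cluster")
    dist = pdist(values, metric="correlation")  # 1 - Pearson r
    Z = linkage(dist, method="average")
    merges = [(int(i), int(j), float(h)) for i, j, h, _ in Z]
    return merges, Z


def expressed_sets(
    matrix: ExpressionMatrix, tau: float = 0.0
) -> dict[str, frozenset[str]]:
    """Per-gene set of sample labels whose normalized value exceeds tau."""
    out = {}
    for gene, row in matrix.df.iterrows():
        out[gene] = frozenset(row.index[row > tau])
    return out


@dataclass(frozen=True)
class PairExpressionCategory:
    gene1: str
    gene2: str
    category: int  # 1 disjoint, 2 identical, 3 subset, 4 partial overlap
    set1: frozenset[str]
    set2: frozenset[str]

    @property
    def category_name(self) -> str:
        return CATEGORY_NAMES[self.category]


def categorize_pair(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    gene1: str = "",
    gene2: str = "",
) -> PairExpressionCategory:
    """Classify the relation between two expressed-tissue sets.

    Disjoint (not both empty) -> 1; equal -> 2 (two empty sets are flagged
    but still 2); proper subset either way -> 3; overlapping with mutual
    exclusive members -> 4. Symmetric up to the subset direction.
    """
    a, b = frozenset(set_a), frozenset(set_b)
    if a == b:
        if not a:
            logger.warning("pair (%s, %s): both sets empty", gene1, gene2)
        category = 2
    elif not (a & b):
        category = 1
    elif a < b or b < a:
        category = 3
    else:
        category = 4
    return PairExpressionCategory(gene1, gene2, category, a, b)


def highest_tissue(matrix: ExpressionMatrix) -> dict[str, str]:
    """Per-gene label of the maximum value; ties go to the first column."""
    out = {}
    for gene, row in matrix.df.iterrows():
        top = row.idxmax()  # first occurrence on ties
        if (row == row.max()).sum() > 1:
            logger.info("tie for highest tissue of %s; kept %s", gene, top)
        out[gene] = top
    return out


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """RT-qPCR fold value relative to the reference gene: 2^-(Ct_t - Ct_r)."""
    if ct_target <= 0 or ct_reference <= 0:
        raise ValueError("cycle thresholds must be positive")
    return 2.0 ** (-(ct_target - ct_reference))
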