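"""Pipeline orchestration: run every stage whose inputs are present and emit
Table-1 / Table-2 style reports with a YAML front-matter provenance block.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .duplication import assign_duplication_type, summarize_duplication
from .expression import (
    ExpressionMatrix,
    categorize_pair,
    expressed_sets,
    genewise_normalize,
)
from .io_formats import (
    read_block_table,
    read_expression_table,
    read_fasta,
    read_locus_table,
)
from .kaks import kaks_for_cds_pair
from .motif_scan import ScanConfig, scan_ccch, summarize_motifs
from .protein_features import detect_tzf, find_nes, phys_chem
from .alignment import smith_waterman
from .subfamily import assign_subfamily

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds for a full run; round-trips through YAML."""

    protein_fasta: str | None = None
    cds_fasta: str | None = None
    locus_table: str | None = None
    block_table: str | None = None
    expression_table: str | None = None
    pairs: list[tuple[str, str]] = field(default_factory=list)
    m_range: tuple[int, int] = (4, 15)
    n_range: tuple[int, int] = (4, 6)
    tandem_max_loci: int = 5
    tandem_max_distance: int = 100_000
    tandem_min_similarity: float = 80.0
    kaks_threshold: float = 0.5
    tau: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tandem_max_loci", "tandem_max_distance",
                     "tandem_min_similarity", "kaks_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("m_range", "n_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "pairs" in raw:
            raw["pairs"] = [tuple(p) for p in raw["pairs"]]
        return cls(**raw)


@dataclass
class ReportBundle:
    gene_table: pd.DataFrame | None = None
    pair_table: pd.DataFrame | None = None
    expression_table: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    @property
    def exit_status(self) -> int:
        """0 full run, 1 partial (stages skipped)."""
        return 1 if self.skipped else 0


def run_all(config: PipelineConfig) -> ReportBundle:
    """Run every stage whose inputs exist; skipped stages are logged."""
    bundle = ReportBundle()
    scan_config = ScanConfig(m_range=config.m_range, n_range=config.n_range)

    proteins = None
    annotations = {}
    if config.protein_fasta:
        proteins = read_fasta(config.protein_fasta, mode="protein")
        rows = []
        for rec in proteins:
            ann = scan_ccch(rec.sequence, scan_config, protein_id=rec.id)
            annotations[rec.id] = ann
            pc = phys_chem(rec.sequence, on_unknown="skip")
            nes = find_nes(rec.sequence)
            tzf = detect_tzf(ann, rec.sequence)
            sub = (assign_subfamily(ann).subfamily if ann.motifs
                   else "unclassified")
            rows.append(
                {
                    "gene_id": rec.id,
                    "length_aa": pc.length,
                    "mol_wt_kd": round(pc.mol_wt / 1000.0, 2),
                    "pi": round(pc.pi, 2),
                    "n_ccch": len(ann),
                    "motif_labels": ";".join(m.label for m in ann.motifs),
                    "subfamily": sub,
                    "n_nes": len(nes),
                    "has_nes": bool(nes),
                    "is_tzf": tzf.is_tzf,
                }
            )
        bundle.gene_table = pd.DataFrame(rows)
        summary = summarize_motifs(list(annotations.values()))
        lengths = bundle.gene_table["length_aa"]
        bundle.summary.update(
            {
                "n_proteins": len(proteins),
                "min_length_aa": int(lengths.min()),
                "max_length_aa": int(lengths.max()),
                "mean_length_aa": round(float(lengths.mean()), 1),
                "pct_with_ge2_motifs": summary.fraction_with_at_least(2),
                "n_with_nes": int(bundle.gene_table["has_nes"].sum()),
                "n_tzf": int(bundle.gene_table["is_tzf"].sum()),
            }
        )
    else:
        bundle.skipped.append("gene_table")
        logger.warning("no protein FASTA: gene table skipped")

    if config.pairs and config.locus_table:
        loci = {l.gene_id: l for l in read_locus_table(config.locus_table)}
        blocks = read_block_table(config.block_table) if config.block_table else []
        cds = (
            {r.id: r.sequence for r in read_fasta(config.cds_fasta, mode="cds")}
            if config.cds_fasta
            else {}
        )
        prot = {p.id: p.sequence for p in proteins} if proteins else {}
        rows = []
        typed = []
        for g1, g2 in config.pairs:
            similarity = (
                smith_waterman(prot[g1], prot[g2]).similarity_pct
                if g1 in prot and g2 in prot
                else 0.0
            )
            pair = assign_duplication_type(
                g1, g2, loci, blocks, similarity,
                max_intervening=config.tandem_max_loci,
                max_distance=config.tandem_max_distance,
                min_similarity=config.tandem_min_similarity,
            )
            typed.append(pair)
            row = {"gene1": g1, "gene2": g2,
                   "duplication": pair.duplication_type,
                   "similarity_pct": round(similarity, 1)}
            if g1 in cds and g2 in cds:
                res = kaks_for_cds_pair(cds[g1], cds[g2],
                                        threshold=config.kaks_threshold)
                row.update(
                    Ks=None if res.Ks is None else round(res.Ks, 4),
                    Ka=None if res.Ka is None else round(res.Ka, 4),
                    ratio=None if res.ratio is None else round(res.ratio, 4),
                    selection=res.selection,
                )
            rows.append(row)
        bundle.pair_table = pd.DataFrame(rows)
        bundle.summary["duplication"] = summarize_duplication(typed)
    else:
        bundle.skipped.append("pair_table")
        logger.warning("no pairs/locus table: pair table skipped")

    if config.expression_table:
        matrix = ExpressionMatrix(read_expression_table(config.expression_table))
        normalized = genewise_normalize(matrix)
        sets = expressed_sets(normalized, tau=config.tau)
        rows = []
        for g1, g2 in config.pairs:
            if g1 in sets and g2 in sets:
                cat = categorize_pair(sets[g1], sets[g2], g1, g2)
                rows.append(
                    {"gene1": g1, "gene2": g2, "category": cat.category,
                     "category_name": cat.category_name,
                     "set1": ",".join(sorted(cat.set1)),
                     "set2": ",".join(sorted(cat.set2)),
                     "tau": config.tau}
                )
        bundle.expression_table = pd.DataFrame(rows)
    else:
        bundle.skipped.append("expression_table")
        logger.warning("no expression table: expression report skipped")

    return bundle


def write_report(df: pd.DataFrame, path: str | Path,
                 config: PipelineConfig) -> None:
    """Write a TSV with a YAML front-matter block (config, version, seed)."""
    front = yaml.safe_dump(
        {"ccchzf_version": __version__, "config": asdict(config)}
    )
    with open(path, "w") as fh:
        for line in front.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
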