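"""Detection and classification of CCCH zinc-finger motifs.

A CCCH motif is the pattern C-X_m-C-X_n-C-X_p-H: three cysteines and one
histidine whose spacer lengths (m, n, p) define the motif class. The two
conventional classes are (7,5,3) and (8,5,3); everything else is
non-conventional. Spacer residues are unrestricted (X = any amino acid,
including C and H), which matters on cysteine-rich sequences and is why the
greedy scanner and the exhaustive mode can differ in motif counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import PROTEIN_ALPHABET

#: spacer patterns of the two conventional motif classes
CONVENTIONAL_CLASSES = frozenset({(7, 5, 3), (8, 5, 3)})

#: motif classes reported for the Populus CCCH family: the two conventional
#: classes plus the non-conventional spacings observed there, including the
#: Populus-unique (11,6,3). Configurable via `classify_motif(catalogue=...)`.
POPULUS_CLASSES = frozenset(
    {
        (7, 5, 3), (8, 5, 3),          # conventional
        (4, 5, 3),                     # widespread non-conventional
        (5, 4, 3), (7, 4, 3), (8, 4, 3),
        (8, 6, 3),
        (9, 5, 3), (11, 5, 3),
        (11, 6, 3),                    # unique to Populus
    }
)

#: abundant in Arabidopsis/rice but never observed in Populus
ABSENT_IN_POPULUS = frozenset({(10, 5, 3)})


def motif_label(m: int, n: int, p: int) -> str:
    return f"C-X{m}-C-X{n}-C-X{p}-H"


@dataclass(frozen=True)
class CcchMotif:
    """One detected C-X_m-C-X_n-C-X_p-H occurrence (0-based start)."""

    start: int
    m: int
    n: int
    p: int = 3

    @property
    def label(self) -> str:
        return motif_label(self.m, self.n, self.p)

    @property
    def spacing(self) -> tuple[int, int, int]:
        return (self.m, self.n, self.p)

    @property
    def span(self) -> int:
        return self.m + self.n + self.p + 4

    @property
    def end(self) -> int:
        """0-based exclusive end (position after the H)."""
        return self.start + self.span

    @property
    def conventional(self) -> bool:
        return self.spacing in CONVENTIONAL_CLASSES


@dataclass
class MotifAnnotation:
    """All motifs found in one protein, sorted by start."""

    protein_id: str
    motifs: list[CcchMotif] = field(default_factory=list)

    @property
    def counts_by_label(self) -> dict[str, int]:
        return dict(Counter(m.label for m in self.motifs))

    def __len__(self) -> int:
        return len(self.motifs)


@dataclass(frozen=True)
class ScanConfig:
    """Spacer ranges (inclusive) and overlap policy for the scanner.

    The defaults cover the conventional classes and the non-conventional
    spacings reported for plant CCCH families; p is fixed at 3 because every
    named class ends C-X3-H, but the range is configurable.
    """

    m_range: tuple[int, int] = (4, 15)
    n_range: tuple[int, int] = (4, 6)
    p_range: tuple[int, int] = (3, 3)
    overlap_policy: str = "greedy_nonoverlap"  # or "all_matches"

    def __post_init__(self) -> None:
        for lo, hi in (self.m_range, self.n_range, self.p_range):
            if lo < 1 or hi < lo:
                raise ValueError(f"bad spacer range ({lo},{hi})")
        if self.overlap_policy not in {"greedy_nonoverlap", "all_matches"}:
            raise ValueError(f"unknown overlap policy {self.overlap_policy!r}")


def _matches_at(seq: str, start: int, m: int, n: int, p: int) -> bool:
    h = start + m + n + p + 3
    if h >= len(seq):
        return False
    return (
        seq[start] == "C"
        and seq[start + m + 1] == "C"
        and seq[start + m + n + 2] == "C"
        and seq[h] == "H"
    )


def _candidates_at(seq: str, start: int, config: ScanConfig) -> list[CcchMotif]:
    out = []
    for m in range(config.m_range[0], config.m_range[1] + 1):
        for n in range(config.n_range[0], config.n_range[1] + 1):
            for p in range(config.p_range[0], config.p_range[1] + 1):
                if _matches_at(seq, start, m, n, p):
                    out.append(CcchMotif(start, m, n, p))
    return out


def scan_ccch(
    seq: str, config: ScanConfig = ScanConfig(), protein_id: str = ""
) -> MotifAnnotation:
    """Scan a protein for CCCH motifs.

    Under ``greedy_nonoverlap`` the sequence is swept left to right; at each
    cysteine every (m, n, p) in range is tried and, among geometric matches,
    the smallest span wins (ties: smallest m), its span is consumed, and the
    sweep resumes after it. Under ``all_matches`` every geometric match is
    returned, overlaps included.
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"illegal residues in sequence: {sorted(bad)}")
    motifs: list[CcchMotif] = []
    if config.overlap_policy == "all_matches":
        for i in range(len(seq)):
            if seq[i] == "C":
                motifs.extend(_candidates_at(seq, i, config))
    else:
        i = 0
        while i < len(seq):
            if seq[i] == "C":
                cands = _candidates_at(seq, i, config)
                if cands:
                    best = min(cands, key=lambda c: (c.span, c.m))
                    motifs.append(best)
                    i = best.end
                    continue
            i += 1
    motifs.sort(key=lambda c: (c.start, c.span, c.m))
    return MotifAnnotation(protein_id=protein_id, motifs=motifs)


def classify_motif(
    m: int,
    n: int,
    p: int,
    catalogue: frozenset[tuple[int, int, int]] = POPULUS_CLASSES,
) -> tuple[str, bool, bool]:
    """Return (canonical label, conventional flag, known-in-Populus flag)."""
    spacing = (m, n, p)
    return (
        motif_label(m, n, p),
        spacing in CONVENTIONAL_CLASSES,
        spacing in catalogue and spacing not in ABSENT_IN_POPULUS,
    )


@dataclass
class FamilySummary:
    """Family-level motif statistics across a set of annotated proteins."""

    n_proteins: int
    motif_counts: dict[str, int]           # protein_id -> number of motifs
    class_totals: dict[str, int]           # motif label -> total occurrences
    count_histogram: dict[int, int]        # motifs-per-protein -> n proteins

    @property
    def total_motifs(self) -> int:
        return sum(self.class_totals.values())

    def fraction_with_at_least(self, k: int) -> float:
        """Percentage of proteins carrying >= k motifs, to one decimal."""
        n = sum(1 for c in self.motif_counts.values() if c >= k)
        return round(100.0 * n / self.n_proteins, 1)


def summarize_motifs(annotations: list[MotifAnnotation]) -> FamilySummary:
    """Aggregate per-protein annotations into family-level counts."""
    if not annotations:
        raise ValueError("no annotations to summarize")
    motif_counts = {a.protein_id: len(a) for a in annotations}
    class_totals: Counter[str] = Counter()
    for a in annotations:
        class_totals.update(a.counts_by_label)
    histogram = Counter(motif_counts.values())
    return FamilySummary(
        n_proteins=len(annotations),
        motif_counts=motif_counts,
        class_totals=dict(class_totals),
        count_histogram=dict(histogram),
    )


def summarize_counts(counts_by_protein: dict[str, int]) -> FamilySummary:
    """Build a family summary from bare per-protein motif counts.

    Used when only tabulated counts are available (no sequences), e.g. when
    auditing a published gene table.
    """
    if not counts_by_protein:
        raise ValueError("no counts to summarize")
    return FamilySummary(
        n_proteins=len(counts_by_protein),
        motif_counts=dict(counts_by_protein),
        class_totals={},
        count_histogram=dict(Counter(counts_by_protein.values())),
    )
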