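"""Duplication typing for paralogous gene pairs.

A pair is classified as segmental/whole-genome (W) when both genes lie
inside the two sides of one homologous duplicated block, tandem (T) when the
genes sit on the same chromosome separated by at most five gene loci and at
most 100 kb with protein similarity of at least 80 %, and other (O)
otherwise. W takes precedence over T: a tandem-looking pair inside a
homologous block pair is still W.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .alignment import smith_waterman  # noqa: F401  (module surface)
from .io_formats import DuplicatedBlock, GeneLocus

logger = logging.getLogger(__name__)

DUPLICATION_TYPES = ("W", "T", "O")

#: tandem-rule defaults: <=5 intervening loci, <=100 kb, >=80 % similarity
MAX_INTERVENING_LOCI = 5
MAX_DISTANCE_BP = 100_000
MIN_SIMILARITY_PCT = 80.0


@dataclass(frozen=True)
class TandemEvidence:
    intervening_loci: int | None
    distance_bp: int | None
    similarity_pct: float
    note: str = ""


@dataclass(frozen=True)
class ParalogPair:
    gene1: str
    gene2: str
    duplication_type: str  # W / T / O
    tandem_evidence: TandemEvidence | None = None
    block_pair_id: str | None = None


def _gene_distance(a: GeneLocus, b: GeneLocus) -> int:
    """Gap in bp between the nearer ends of two gene intervals (0 if they
    overlap); coordinates are 1-based inclusive."""
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end - 1)


def is_tandem(
    a: GeneLocus,
    b: GeneLocus,
    similarity_pct: float,
    max_intervening: int = MAX_INTERVENING_LOCI,
    max_distance: int = MAX_DISTANCE_BP,
    min_similarity: float = MIN_SIMILARITY_PCT,
) -> tuple[bool, TandemEvidence]:
    """Apply the tandem-duplicate rule; symmetric in its two loci.

    Different chromosomes is a negative call with explanatory evidence, not
    an error.
    """
    if a.chrom_label != b.chrom_label:
        return False, TandemEvidence(None, None, similarity_pct,
                                     "different_chromosome")
    intervening = abs(a.locus_index - b.locus_index) - 1
    distance = _gene_distance(a, b)
    ok = (
        intervening <= max_intervening
        and distance <= max_distance
        and similarity_pct >= min_similarity
    )
    return ok, TandemEvidence(intervening, distance, similarity_pct)


def assign_duplication_type(
    gene1: str,
    gene2: str,
    loci: dict[str, GeneLocus],
    blocks: list[DuplicatedBlock],
    similarity_pct: float,
    **tandem_kwargs,
) -> ParalogPair:
    """Type one paralogous pair as W, T or O (mutually exclusive)."""
    for g in (gene1, gene2):
        if g not in loci:
            raise KeyError(f"gene {g} absent from locus table")
    l1, l2 = loci[gene1], loci[gene2]
    for block in blocks:
        if (block.contains(l1, "a") and block.contains(l2, "b")) or (
            block.contains(l1, "b") and block.contains(l2, "a")
        ):
            return ParalogPair(gene1, gene2, "W", block_pair_id=block.block_id)
    tandem, evidence = is_tandem(l1, l2, similarity_pct, **tandem_kwargs)
    if tandem:
        return ParalogPair(gene1, gene2, "T", tandem_evidence=evidence)
    return ParalogPair(gene1, gene2, "O", tandem_evidence=evidence)


def summarize_duplication(pairs: list[ParalogPair]) -> dict:
    """Counts and one-decimal percentages per duplication type."""
    if not pairs:
        raise ValueError("no pairs to summarize")
    counts = {t: 0 for t in DUPLICATION_TYPES}
    for p in pairs:
        counts[p.duplication_type] += 1
    total = len(pairs)
    return {
        "counts": counts,
        "percentages": {t: round(100.0 * c / total, 1) for t, c in counts.items()},
        "total": total,
    }
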