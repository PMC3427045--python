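"""Ka/Ks estimation for coding-sequence pairs (Nei-Gojobori 1986 counting).

The pipeline is: global protein alignment (Needleman-Wunsch, shared affine
machinery), threading the guide alignment back onto the in-frame CDS pairs,
then NG86: per-codon synonymous/nonsynonymous site counting by enumerating
the three single-nucleotide mutations at each position (mutations creating
stop codons are excluded from the averaging denominator), pathway-averaged
difference counting for multi-substitution codons, and the Jukes-Cantor
multiple-hit correction d = -(3/4) ln(1 - 4p/3).

Selection is called purifying when Ka/Ks falls below a threshold of 0.5 (the
conventional neutrality threshold 1.0 is available via the ``threshold``
argument).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .alignment import AlignmentResult, needleman_wunsch  # noqa: F401

logger = logging.getLogger(__name__)

_TABLE = unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"

GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _STOPS:
    GENETIC_CODE[_stop] = "*"


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free, stop-free list of aligned codon pairs."""

    codon_pairs: tuple[tuple[str, str], ...]
    n_dropped: int = 0  # gap / stop / ambiguous codon columns removed

    def __len__(self) -> int:
        return len(self.codon_pairs)


@dataclass(frozen=True)
class KaKsResult:
    S: float          # synonymous sites (fractional)
    N: float          # nonsynonymous sites
    Sd: float         # observed synonymous differences
    Nd: float         # observed nonsynonymous differences
    pS: float
    pN: float
    Ks: float | None  # None when the JC correction is undefined (p >= 3/4)
    Ka: float | None
    ratio: float | None  # Ka/Ks, defined only when Ks > 0
    selection: str       # purifying / relaxed_or_positive / undefined


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS, trimming one trailing stop codon."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    seq = str(Seq(cds).translate())
    if seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        raise ValueError(f"internal stop codon at aa {seq.index('*') + 1}")
    return seq


def thread_codons(
    guide: AlignmentResult, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Map a protein guide alignment back onto the two CDSs.

    Requires translate(cds) to equal the corresponding ungapped protein row;
    columns with a gap on either side are dropped, as are codon pairs
    containing a stop codon or an ambiguous base (counted, logged).
    """
    prot_a = guide.aligned_a.replace("-", "")
    prot_b = guide.aligned_b.replace("-", "")
    cds_a = cds_a[: 3 * len(prot_a) + 3]  # tolerate one trailing stop
    cds_b = cds_b[: 3 * len(prot_b) + 3]
    for label, prot, cds in (("a", prot_a, cds_a), ("b", prot_b, cds_b)):
        trans = translate_cds(cds)
        if trans != prot:
            pos = next(
                (k for k, (x, y) in enumerate(zip(trans, prot)) if x != y),
                min(len(trans), len(prot)),
            )
            raise ValueError(
                f"CDS {label} does not translate to the aligned protein "
                f"(first mismatch at aa {pos + 1})"
            )
    pairs: list[tuple[str, str]] = []
    dropped = 0
    ia = ib = 0
    for ca, cb in zip(guide.aligned_a, guide.aligned_b):
        if ca == "-" or cb == "-":
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
            dropped += 1
            continue
        codon_a = cds_a[3 * ia : 3 * ia + 3]
        codon_b = cds_b[3 * ib : 3 * ib + 3]
        ia += 1
        ib += 1
        if (
            codon_a in _STOPS
            or codon_b in _STOPS
            or set(codon_a + codon_b) - set(_BASES)
        ):
            dropped += 1
            continue
        pairs.append((codon_a, codon_b))
    if dropped:
        logger.info("thread_codons: dropped %d columns", dropped)
    return CodonAlignment(tuple(pairs), n_dropped=dropped)


@lru_cache(maxsize=None)
def syn_sites(codon: str) -> float:
    """NG86 synonymous-site count of one codon.

    Each position contributes the fraction of its single-nucleotide
    mutations that are synonymous, with mutations to stop codons removed
    from the denominator; positions whose every mutation creates a stop
    contribute zero. The three positions always sum (syn + nonsyn) to 3.
    """
    aa = GENETIC_CODE[codon]
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in _STOPS:
                continue
            valid += 1
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Codons differing at k positions are resolved by averaging over all k!
    orderings of single-nucleotide steps with equal weight; pathways passing
    through a stop codon are excluded (all-blocked falls back to using every
    pathway, which cannot occur for sense codons under the standard code at
    k <= 2 but guards k = 3).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    results: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        (blocked if through_stop else results).append((syn, nonsyn))
    if not results:
        results = blocked
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(alignment: CodonAlignment, threshold: float = 0.5) -> KaKsResult:
    """Estimate Ka, Ks and Ka/Ks from a codon alignment by NG86 counting."""
    if len(alignment) == 0:
        raise ValueError("empty codon alignment")
    S = sum(
        (syn_sites(a) + syn_sites(b)) / 2.0 for a, b in alignment.codon_pairs
    )
    N = 3.0 * len(alignment) - S
    Sd = Nd = 0.0
    for a, b in alignment.codon_pairs:
        sd, nd = codon_differences(a, b)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    if Ks is None:
        logger.warning("pS = %.3f >= 3/4: Ks undefined", pS)
    if Ka is None:
        logger.warning("pN = %.3f >= 3/4: Ka undefined", pN)
    ratio = None
    if Ks is not None and Ka is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio,
        selection=classify_selection(ratio, threshold),
    )


def classify_selection(ratio: float | None, threshold: float = 0.5) -> str:
    """purifying below the threshold, relaxed_or_positive at or above it,
    undefined when the ratio itself is undefined (e.g. Ks = 0)."""
    if ratio is None:
        return "undefined"
    return "purifying" if ratio < threshold else "relaxed_or_positive"


def kaks_for_cds_pair(
    cds_a: str, cds_b: str, threshold: float = 0.5
) -> KaKsResult:
    """Convenience wrapper: align the translations, thread, and count."""
    prot_a = translate_cds(cds_a)
    prot_b = translate_cds(cds_b)
    guide = needleman_wunsch(prot_a, prot_b)
    return ng86(thread_codons(guide, cds_a, cds_b), threshold=threshold)
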