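"""Protein-level features: NES scan, tandem zinc finger (TZF) architecture,
and physicochemical statistics (length, molecular weight, isoelectric point).

The nuclear export signal (NES) is the leucine-rich consensus
``[LV]-x(2,3)-[LIVFM]-x(2,3)-L-x-[LIMTKD]`` (9-11 residues). A TZF protein
carries two identical C-X8-C-X5-C-X3-H motifs separated by a fixed spacer
(18 residues by default), the architecture associated with ARE-mediated mRNA
decay; its five-residue lead-in is extracted for reporting only, never used
as a filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .motif_scan import CcchMotif, MotifAnnotation

logger = logging.getLogger(__name__)

_NES_SLOT1 = set("LV")
_NES_SLOT2 = set("LIVFM")
_NES_SLOT4 = set("LIMTKD")


@dataclass(frozen=True)
class NesMatch:
    """One NES consensus occurrence; end is 0-based exclusive."""

    start: int
    end: int
    matched_text: str


def find_nes(seq: str) -> list[NesMatch]:
    """Scan for all NES consensus match positions.

    Every start position with at least one spacer-width combination matching
    is reported exactly once, recording the shortest match there. The scan is
    a direct slot-by-slot sweep (the regex formulation is kept for
    cross-checking in tests, not used here).
    """
    matches: list[NesMatch] = []
    n = len(seq)
    for i in range(n):
        if seq[i] not in _NES_SLOT1:
            continue
        found = None
        # try widths shortest-total first: (2,2) < (2,3) < (3,2) < (3,3)
        for x1, x2 in sorted(
            ((a, b) for a in (2, 3) for b in (2, 3)), key=lambda w: (sum(w), w)
        ):
            j2 = i + 1 + x1            # [LIVFM]
            j3 = j2 + 1 + x2           # L
            j5 = j3 + 2                # [LIMTKD]
            if j5 >= n:
                continue
            if seq[j2] in _NES_SLOT2 and seq[j3] == "L" and seq[j5] in _NES_SLOT4:
                found = NesMatch(i, j5 + 1, seq[i : j5 + 1])
                break
        if found is not None:
            matches.append(found)
    return matches


@dataclass(frozen=True)
class TzfCall:
    """TZF architecture call for one protein."""

    is_tzf: bool
    motif1_start: int = -1
    motif2_start: int = -1
    spacer_len: int = -1
    leadin: str = ""


def detect_tzf(
    annotation: MotifAnnotation, seq: str, spacing: int = 18
) -> TzfCall:
    """Decide whether a protein has the tandem-zinc-finger architecture.

    True iff some ordered pair of motifs are both (8,5,3) and the number of
    residues strictly between the H of the first and the first C of the
    second equals ``spacing``. The separation is measured exclusively at both
    ends; the lead-in is the up-to-5 residues preceding motif 1.
    """
    fingers = [m for m in annotation.motifs if m.spacing == (8, 5, 3)]
    for first in fingers:
        for second in fingers:
            if second.start <= first.start:
                continue
            gap = second.start - first.end
            if gap == spacing:
                leadin = seq[max(0, first.start - 5) : first.start]
                return TzfCall(True, first.start, second.start, gap, leadin)
    return TzfCall(False)


# -- physicochemical parameters ----------------------------------------------

#: average (not monoisotopic) residue masses, Da
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER = 18.01524

#: EMBOSS pKa values (iep defaults); DNAman's constants are unpublished,
#: so pI agreement with published tables is expected only to ~0.3 pH units.
PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


@dataclass(frozen=True)
class PhysChem:
    length: int
    mol_wt: float  # Daltons
    pi: float      # pH units


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge over termini and D,E,C,Y,H,K,R."""
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa in seq:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def phys_chem(seq: str, on_unknown: str = "error") -> PhysChem:
    """Length, average-mass molecular weight, and bisection-solved pI.

    ``on_unknown`` controls X handling: "error" raises, "skip" drops X
    residues from the mass/charge sums with a warning (length still counts
    the full sequence).
    """
    if not seq:
        raise ValueError("empty sequence")
    length = len(seq)
    if "X" in seq:
        if on_unknown == "error":
            raise ValueError("sequence contains unknown residue X")
        logger.warning("skipping %d X residues in phys_chem", seq.count("X"))
        seq = seq.replace("X", "")
        if not seq:
            raise ValueError("sequence is all X")
    bad = set(seq) - set(_RESIDUE_MASS)
    if bad:
        raise ValueError(f"unknown residues: {sorted(bad)}")
    mol_wt = sum(_RESIDUE_MASS[aa] for aa in seq) + _WATER
    # net charge is strictly decreasing in pH, so bisection converges
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    pi = (lo + hi) / 2.0
    if abs(net_charge(seq, pi)) > 1e-4 and not (pi < 1e-3 or pi > 14 - 1e-3):
        logger.warning("pI bisection residual charge %.2e", net_charge(seq, pi))
    return PhysChem(length=length, mol_wt=mol_wt, pi=pi)
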