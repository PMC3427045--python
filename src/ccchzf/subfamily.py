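"""Motif-composition subfamily taxonomy (CCCH-a ... CCCH-e).

Each protein is assigned a class from the multiset of its CCCH motif
spacings alone:

* CCCH-a: 1-3 motifs, all (7,5,3)
* CCCH-b: 1-6 motifs, all (8,5,3)
* CCCH-c: 2-3 motifs including at least one (7,5,3) and one (8,5,3)
* CCCH-d: exactly one (5,4,3) plus exactly one of (7,5,3)/(8,5,3)/(10,5,3)
* CCCH-e: any remaining composition containing a non-conventional motif

The published rules overlap (a two-motif (7,5,3)+(8,5,3) protein is a prefix
of several of them), so they are tested in the fixed precedence
d -> c -> a -> b -> e, letting the more specific composite rules win.
Compositions of only-conventional motifs outside the stated count ranges are
left unclassified rather than forced, treating the ranges as definitional.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .motif_scan import CONVENTIONAL_CLASSES, MotifAnnotation

SUBFAMILIES = ("CCCH-a", "CCCH-b", "CCCH-c", "CCCH-d", "CCCH-e")


@dataclass(frozen=True)
class SubfamilyCall:
    protein_id: str
    subfamily: str  # one of SUBFAMILIES or "unclassified"
    rationale: str


def assign_subfamily(annotation: MotifAnnotation) -> SubfamilyCall:
    """Classify one protein from its motif composition (order-insensitive)."""
    if not annotation.motifs:
        raise ValueError(
            f"{annotation.protein_id or 'protein'} has no CCCH motifs; "
            "not a CCCH protein"
        )
    comp = Counter(m.spacing for m in annotation.motifs)
    total = sum(comp.values())
    pid = annotation.protein_id

    n753 = comp.get((7, 5, 3), 0)
    n853 = comp.get((8, 5, 3), 0)
    n543 = comp.get((5, 4, 3), 0)
    n_partner_d = n753 + n853 + comp.get((10, 5, 3), 0)

    if n543 == 1 and n_partner_d == 1 and total == 2:
        return SubfamilyCall(
            pid, "CCCH-d",
            "one (5,4,3) paired with one (7,5,3)/(8,5,3)/(10,5,3) [rule d]",
        )
    if n753 >= 1 and n853 >= 1 and 2 <= total <= 3:
        return SubfamilyCall(
            pid, "CCCH-c",
            f"{total} motifs mixing (7,5,3) and (8,5,3) [rule c]",
        )
    if n753 == total and 1 <= total <= 3:
        return SubfamilyCall(
            pid, "CCCH-a", f"{total} x (7,5,3) only [rule a]"
        )
    if n853 == total and 1 <= total <= 6:
        return SubfamilyCall(
            pid, "CCCH-b", f"{total} x (8,5,3) only [rule b]"
        )
    if any(s not in CONVENTIONAL_CLASSES for s in comp):
        return SubfamilyCall(
            pid, "CCCH-e", "contains a non-conventional motif [rule e]"
        )
    return SubfamilyCall(
        pid, "unclassified",
        f"only-conventional composition outside rule ranges ({total} motifs)",
    )
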