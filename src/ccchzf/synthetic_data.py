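"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the study's inputs: proteomes with planted CCCH
motifs, NES instances and TZF architectures; gene maps with planted tandem
arrays and homologous duplicated-block pairs; codon-sequence pairs evolved
at a known dN/dS; and expression matrices with planted paralog-divergence
categories.

Proteome backgrounds are drawn from the 20 standard residues minus C, H and
L: excluding C and H makes the planted motif geometry the only one present
(exact motif truth), and excluding L removes the mandatory leucine of the
NES consensus so an unplanted NES cannot arise by chance. A full-alphabet
"hard mode" is available for stress testing; its motif truth must then be
recomputed with an exhaustive scanner rather than taken from the plants.

Every generator is a pure function of (config, seed): identical arguments
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import CdsRecord, DuplicatedBlock, GeneLocus, ProteinRecord
from .kaks import GENETIC_CODE

#: background residues: 20 standard minus C, H (motif truth) and L (NES truth)
BACKGROUND_RESIDUES = "ADEFGIKMNPQRSTVWY"
FULL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
_BASES = "ACGT"


# -- proteomes ---------------------------------------------------------------

@dataclass(frozen=True)
class PlantedMotif:
    start: int
    spacing: tuple[int, int, int]


@dataclass
class ProteinTruth:
    protein_id: str
    motifs: list[PlantedMotif] = field(default_factory=list)
    nes_starts: list[int] = field(default_factory=list)
    is_tzf: bool = False

    @property
    def has_nes(self) -> bool:
        return bool(self.nes_starts)


def _bg(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _motif_string(rng, spacing, alphabet) -> str:
    m, n, p = spacing
    return (
        "C" + _bg(rng, m, alphabet)
        + "C" + _bg(rng, n, alphabet)
        + "C" + _bg(rng, p, alphabet)
        + "H"
    )


def _nes_string(rng) -> str:
    """One instantiation of [LV]-x(2,3)-[LIVFM]-x(2,3)-L-x-[LIMTKD]."""
    pick = lambda s: s[rng.integers(0, len(s))]
    x1 = int(rng.integers(2, 4))
    x2 = int(rng.integers(2, 4))
    return (
        pick("LV")
        + _bg(rng, x1, BACKGROUND_RESIDUES)
        + pick("LIVFM")
        + _bg(rng, x2, BACKGROUND_RESIDUES)
        + "L"
        + _bg(rng, 1, BACKGROUND_RESIDUES)
        + pick("LIMTKD")
    )


def gen_proteome(
    n_proteins: int,
    motif_spec: list[tuple[tuple[int, int, int], tuple[int, int]]] | None = None,
    nes_rate: float = 0.0,
    tzf_rate: float = 0.0,
    length_range: tuple[int, int] = (150, 400),
    seed: int = 0,
    tzf_spacing: int = 18,
    hard_mode: bool = False,
) -> tuple[list[ProteinRecord], list[ProteinTruth]]:
    """Generate a proteome with planted motifs, NES matches and TZF pairs.

    ``motif_spec`` lists (spacing, (min_copies, max_copies)) entries; copy
    numbers are drawn uniformly per protein and entry. A TZF protein gets
    two (8,5,3) motifs separated by exactly ``tzf_spacing`` residues in
    place of its spec-drawn motifs. Planted elements are separated by at
    least one background residue; an error is raised if they cannot be
    packed into the drawn length.
    """
    if motif_spec is None:
        motif_spec = [((7, 5, 3), (0, 2)), ((8, 5, 3), (0, 2)),
                      ((5, 4, 3), (0, 1))]
    alphabet = FULL_RESIDUES if hard_mode else BACKGROUND_RESIDUES
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truths: list[ProteinTruth] = []
    for k in range(n_proteins):
        pid = f"syn{k + 1:04d}"
        truth = ProteinTruth(protein_id=pid)
        is_tzf = rng.random() < tzf_rate
        pieces: list[tuple[str, str]] = []  # (kind, text)
        if is_tzf:
            m1 = _motif_string(rng, (8, 5, 3), alphabet)
            spacer = _bg(rng, tzf_spacing, alphabet)
            m2 = _motif_string(rng, (8, 5, 3), alphabet)
            pieces.append(("tzf", m1 + spacer + m2))
        else:
            planted: list[tuple[int, int, int]] = []
            for spacing, (lo, hi) in motif_spec:
                for _ in range(int(rng.integers(lo, hi + 1))):
                    planted.append(spacing)
            if not planted:
                planted.append(motif_spec[0][0])
            for spacing in planted:
                pieces.append(("motif:%d,%d,%d" % spacing,
                               _motif_string(rng, spacing, alphabet)))
        if rng.random() < nes_rate:
            pieces.append(("nes", _nes_string(rng)))
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        needed = sum(len(t) for _, t in pieces) + len(pieces) + 1
        if needed > length:
            raise ValueError(
                f"{pid}: planted elements ({needed} aa) exceed length {length}"
            )
        # distribute remaining background around the pieces
        slack = length - needed
        n_gaps = len(pieces) + 1
        extra = rng.multinomial(slack, [1.0 / n_gaps] * n_gaps)
        seq_parts = [_bg(rng, 1 + int(extra[0]), alphabet)]
        pos = len(seq_parts[0])
        for idx, (kind, text) in enumerate(pieces):
            if kind == "tzf":
                truth.is_tzf = True
                truth.motifs.append(PlantedMotif(pos, (8, 5, 3)))
                truth.motifs.append(
                    PlantedMotif(pos + 20 + tzf_spacing, (8, 5, 3))
                )
            elif kind.startswith("motif:"):
                spacing = tuple(int(x) for x in kind[6:].split(","))
                truth.motifs.append(PlantedMotif(pos, spacing))
            else:
                truth.nes_starts.append(pos)
            seq_parts.append(text)
            pos += len(text)
            gap = 1 + int(extra[idx + 1])
            seq_parts.append(_bg(rng, gap, alphabet))
            pos += gap
        records.append(ProteinRecord(id=pid, sequence="".join(seq_parts)))
        truths.append(truth)
    return records, truths


# -- gene maps ---------------------------------------------------------------

@dataclass
class GeneMapTruth:
    loci: list[GeneLocus]
    blocks: list[DuplicatedBlock]
    pairs: list[tuple[str, str, str]]  # (gene1, gene2, W/T/O)


def gen_gene_map(
    n_chrom: int = 4,
    genes_per_chrom: int = 20,
    n_tandem_arrays: int = 3,
    n_block_pairs: int = 4,
    n_other_pairs: int = 2,
    seed: int = 0,
    block_width: int = 2,
    tandem_gap: tuple[int, int] = (5_000, 60_000),
) -> GeneMapTruth:
    """Generate a gene map with planted tandem arrays and block pairs.

    Tandem arrays (two genes, <= 5 intervening loci trivially, gap drawn
    within 100 kb) occupy the low locus indices of each chromosome; block
    pairs pair windows of ``block_width`` genes in the high indices of two
    different chromosomes, so planted W and T pairs can never collide.
    Default intergenic gaps (150-250 kb) keep unplanted neighbours from
    satisfying the tandem distance rule.
    """
    if genes_per_chrom < block_width + 8:
        raise ValueError("genes_per_chrom too small for the planted layout")
    rng = np.random.default_rng(seed)
    gaps: dict[str, list[int]] = {}
    gene_len: dict[str, list[int]] = {}
    chroms = [f"chr{c + 1}" for c in range(n_chrom)]
    for chrom in chroms:
        gaps[chrom] = [int(rng.integers(150_000, 250_000))
                       for _ in range(genes_per_chrom)]
        gene_len[chrom] = [int(rng.integers(1_000, 3_000))
                           for _ in range(genes_per_chrom)]

    pairs: list[tuple[str, str, str]] = []
    # tandem arrays in low indices (gene ranks 1..6)
    for t in range(n_tandem_arrays):
        chrom = chroms[t % n_chrom]
        first = 2 * (t // n_chrom)  # 0-based index of the first array gene
        if first + 1 >= 6:
            raise ValueError("too many tandem arrays for the reserved region")
        gaps[chrom][first + 1] = int(rng.integers(*tandem_gap))
        pairs.append(
            (f"{chrom}_g{first + 1:03d}", f"{chrom}_g{first + 2:03d}", "T")
        )

    # lay out coordinates
    loci: list[GeneLocus] = []
    coords: dict[str, list[tuple[int, int]]] = {}
    for chrom in chroms:
        pos = 1
        coords[chrom] = []
        for i in range(genes_per_chrom):
            pos += gaps[chrom][i]
            start, end = pos, pos + gene_len[chrom][i] - 1
            coords[chrom].append((start, end))
            loci.append(
                GeneLocus(f"{chrom}_g{i + 1:03d}", chrom, start, end,
                          "+" if rng.random() < 0.5 else "-", i + 1)
            )
            pos = end + 1

    # block pairs in high indices (last half of each chromosome)
    blocks: list[DuplicatedBlock] = []
    hi0 = genes_per_chrom // 2
    for bk in range(n_block_pairs):
        c1 = chroms[bk % n_chrom]
        c2 = chroms[(bk + 1) % n_chrom]
        # disjoint index windows so no gene belongs to two planted pairs
        i1 = hi0 + block_width * bk
        i2 = i1
        if i1 + block_width > genes_per_chrom:
            raise ValueError("too many block pairs for the reserved region")
        a_lo, a_hi = coords[c1][i1][0] - 100, coords[c1][i1 + block_width - 1][1] + 100
        b_lo, b_hi = coords[c2][i2][0] - 100, coords[c2][i2 + block_width - 1][1] + 100
        blocks.append(
            DuplicatedBlock(f"B{bk + 1}", (c1, a_lo, a_hi), (c2, b_lo, b_hi))
        )
        for t in range(block_width):
            pairs.append(
                (f"{c1}_g{i1 + t + 1:03d}", f"{c2}_g{i2 + t + 1:03d}", "W")
            )

    # O pairs: cross-chromosome genes below the block region, above tandem
    for o in range(n_other_pairs):
        c1 = chroms[o % n_chrom]
        c2 = chroms[(o + 2) % n_chrom]
        if c1 == c2:
            raise ValueError("need >= 3 chromosomes for planted O pairs")
        idx = 7 + o
        if idx >= hi0:
            raise ValueError("too many O pairs for the reserved region")
        pairs.append((f"{c1}_g{idx + 1:03d}", f"{c2}_g{idx + 1:03d}", "O"))

    return GeneMapTruth(loci=loci, blocks=blocks, pairs=pairs)


# -- codon pairs -------------------------------------------------------------

@dataclass
class CdsPairTruth:
    pair_id: str
    omega: float
    n_syn_events: int
    n_nonsyn_events: int


def _mutate_cds(
    rng: np.random.Generator, cds: list[str], omega: float, n_events: int
) -> tuple[list[str], int, int]:
    """Acceptance-thinning substitution process on a codon list.

    Proposals are uniform single-nucleotide changes; those creating stop
    codons are rejected outright; synonymous proposals are accepted with
    probability 1 and nonsynonymous ones with probability omega.
    """
    n_syn = n_nonsyn = 0
    n_sites = 3 * len(cds)
    while n_syn + n_nonsyn < n_events:
        site = int(rng.integers(0, n_sites))
        ci, pos = divmod(site, 3)
        codon = cds[ci]
        base = _BASES[rng.integers(0, 4)]
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if GENETIC_CODE[mutant] == "*":
            continue
        if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
            cds[ci] = mutant
            n_syn += 1
        elif rng.random() < omega:
            cds[ci] = mutant
            n_nonsyn += 1
    return cds, n_syn, n_nonsyn


def gen_cds_pairs(
    n_pairs: int,
    n_codons: int = 300,
    omega: float = 0.3,
    expected_sub_per_codon: float = 0.2,
    seed: int = 0,
) -> tuple[list[tuple[CdsRecord, CdsRecord]], list[CdsPairTruth]]:
    """Simulate CDS pairs: random sense-codon ancestor plus a mutated copy.

    The number of accepted substitutions per pair is Poisson with mean
    ``expected_sub_per_codon * n_codons``. The simulator is a simple
    acceptance-thinning process (not a full codon model): adequate for NG86
    recovery checks, and documented as such.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[CdsRecord, CdsRecord]] = []
    truths: list[CdsPairTruth] = []
    for k in range(n_pairs):
        ancestor = [SENSE_CODONS[i]
                    for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
        n_events = int(rng.poisson(expected_sub_per_codon * n_codons))
        derived, n_syn, n_nonsyn = _mutate_cds(
            rng, list(ancestor), omega, n_events
        )
        pid = f"pair{k + 1:04d}"
        pairs.append(
            (
                CdsRecord(id=f"{pid}_a", sequence="".join(ancestor)),
                CdsRecord(id=f"{pid}_b", sequence="".join(derived)),
            )
        )
        truths.append(CdsPairTruth(pid, omega, n_syn, n_nonsyn))
    return pairs, truths


# -- expression matrices -----------------------------------------------------

@dataclass
class ExpressionTruth:
    gene1: str
    gene2: str
    category: int
    set1: frozenset[str]
    set2: frozenset[str]


def _sets_for_category(
    rng: np.random.Generator, labels: tuple[str, ...], category: int
) -> tuple[frozenset[str], frozenset[str]]:
    """Draw two expressed-tissue sets realizing the requested relation.

    Set sizes are kept between 2 and len(labels)-2 (1 and len-1 for tiny
    label universes): near-full and near-empty sets leave an above-the-mean
    threshold almost no margin over the row mean, so moderate noise would
    corrupt the planted relation rather than test its recovery.
    """
    n = len(labels)
    lo = 2 if n >= 6 else 1
    hi = n - lo
    if hi < lo or (category == 3 and hi == lo):
        raise ValueError(f"label universe of {n} too small for category {category}")
    perm = [labels[i] for i in rng.permutation(n)]
    if category == 1:  # disjoint
        k1 = int(rng.integers(lo, min(hi, n - lo) + 1))
        k2 = int(rng.integers(lo, min(hi, n - k1) + 1))
        return frozenset(perm[:k1]), frozenset(perm[k1 : k1 + k2])
    if category == 2:  # identical
        s = frozenset(perm[: int(rng.integers(lo, hi + 1))])
        return s, s
    if category == 3:  # proper subset
        k_small = int(rng.integers(lo, hi))
        k_big = int(rng.integers(k_small + 1, hi + 1))
        small = frozenset(perm[:k_small])
        big = frozenset(perm[:k_big])
        return (small, big) if rng.random() < 0.5 else (big, small)
    if category == 4:  # partial overlap: shared core + mutual exclusives
        if n < lo + 2:
            raise ValueError("partial overlap needs a larger label universe")
        shared = int(rng.integers(max(1, lo - 1), hi - 1 + 1))
        s1 = frozenset(perm[: shared + 1])
        s2 = frozenset(perm[:shared] + [perm[shared + 1]])
        return s1, s2
    raise ValueError(f"unknown category {category}")


def gen_expression(
    pair_categories: list[int],
    labels: tuple[str, ...] = ("Rt", "ML", "YL", "FC", "MC", "XL"),
    noise_sd: float = 0.0,
    seed: int = 0,
    signal: float = 1.0,
) -> tuple["np.ndarray", list[str], list[str], list[ExpressionTruth]]:
    """Expression matrix with planted paralog-divergence categories.

    Returns (values, gene_ids, sample_labels, truths). Each planted gene's
    row is ``+signal`` on its expressed labels and ``-signal`` elsewhere,
    plus Gaussian noise; with the bounded set sizes every label then sits at
    least 2/3 of a signal unit away from the row mean, so the above-mean set
    after gene-wise normalization equals the planted set whenever the noise
    is small relative to the signal.
    """
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    truths: list[ExpressionTruth] = []
    for k, category in enumerate(pair_categories):
        s1, s2 = _sets_for_category(rng, labels, category)
        g1, g2 = f"pair{k + 1:03d}_a", f"pair{k + 1:03d}_b"
        for gid, s in ((g1, s1), (g2, s2)):
            base = np.array(
                [signal if lab in s else -signal for lab in labels],
                dtype=float,
            )
            rows.append(base + rng.normal(0.0, noise_sd, len(labels)))
            gene_ids.append(gid)
        truths.append(ExpressionTruth(g1, g2, category, s1, s2))
    return np.vstack(rows), gene_ids, list(labels), truths
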