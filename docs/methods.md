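# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, the design decisions taken where a published
description was ambiguous, and what the synthetic-data generators do and do
not emulate.

## CCCH motif scanning

A motif is the geometric pattern C-X<sub>m</sub>-C-X<sub>n</sub>-C-X<sub>p</sub>-H
with the cysteines at offsets 0, m+1, m+n+2 and the histidine at m+n+p+3
from the start; its span is m+n+p+4 residues. Spacer residues are
unrestricted — X may itself be C or H. This follows the notation literally
and matters on cysteine-rich sequences, where restricting spacers would
change motif counts.

Default ranges are m ∈ [4, 15], n ∈ [4, 6], p = 3, covering the two
conventional classes (7,5,3) and (8,5,3) and the non-conventional spacings
reported for plant families; p is fixed at 3 because every named class ends
C-X<sub>3</sub>-H, but the range is configurable.

Because matches can overlap, the default **greedy non-overlap** policy
sweeps left to right and, at each cysteine with at least one geometric
match, accepts the candidate with the smallest span (ties: smallest m),
consumes it, and resumes after it. This resolution is a package convention —
published family tables report only final counts. The `all_matches` policy
returns every geometric match so users can audit the greedy choice; tests
check the greedy result against an independent exhaustive enumeration
followed by the same sweep.

The motif catalogue used by `classify_motif` flags the (11,6,3) class as
unique to *Populus* and (10,5,3) as absent from it; both facts are data
about one genome, so the catalogue is an argument, not a constant.

## NES and TZF detection

The NES scan implements the leucine-rich consensus
`[LV]-x(2,3)-[LIVFM]-x(2,3)-L-x-[LIMTKD]` (match length 9–11) with a direct
slot-by-slot sweep; each start position is reported once with the shortest
width combination that matches there. A regex formulation of the same
consensus serves as the independent oracle in tests. Per-protein presence
(`has_nes`) is what downstream reports use.

A TZF call requires two (8,5,3) motifs with exactly 18 residues strictly
between the histidine of the first and the first cysteine of the second.
The "separated by 18 amino acids" convention is measured exclusively at
both ends because the source material does not define the endpoints; the
spacing is a parameter. The five residues preceding the first finger (the
lead-in, part of the RNA-binding surface in characterized TZF proteins) are
extracted for reporting but never used as a filter — the published lead-in
consensus is too ambiguous to encode.

## Physicochemical parameters

Molecular weight is the sum of average (not monoisotopic) residue masses
plus one water (18.01524 Da). The isoelectric point solves net charge = 0
by bisection on [0, 14] to a pH interval of 1e-6, using
Henderson–Hasselbalch terms for the termini and D, E, C, Y (acidic), H, K,
R (basic) with the EMBOSS pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9,
E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1). Published family tables were
produced with a commercial tool whose constants are unpublished, so pI
agreement beyond ~0.3 pH units is not expected and not asserted. Unknown
residues (X) either raise or are skipped from the mass/charge sums,
per configuration; the reported length always counts the full sequence.

## Subfamily taxonomy (CCCH-a…e)

Classification is a total, order-insensitive function of the multiset of
motif spacings. The published rules overlap, so they are tested in the
fixed precedence **d → c → a → b → e** (most specific composite rules
first): d is exactly one (5,4,3) plus exactly one of (7,5,3)/(8,5,3)/
(10,5,3); c is 2–3 motifs including at least one (7,5,3) and one (8,5,3)
(the "2–3" is read as bounding the total, one of two possible readings);
a is 1–3 × (7,5,3) only; b is 1–6 × (8,5,3) only; e is any remaining
composition containing a non-conventional motif. Only-conventional
compositions outside the stated count ranges are left `unclassified`
rather than forced, treating the ranges as definitional. The 13-subfamily
phylogenetic classification of the family is tree-based and out of scope.

## Alignment

Local (Smith–Waterman) and global (Needleman–Wunsch) alignment share a
Gotoh three-state affine-gap DP. Gap costs follow the EMBOSS convention of
the EBI tools the similarity figures were produced with: a gap of length L
costs `gap_open + (L−1)·gap_extend`, defaults BLOSUM62 / 10 / 0.5.
Traceback is deterministic: the local start cell is the maximal match-state
cell with ties to the smallest row then column, and move preference is
diagonal > up > left. `identity_pct` counts identical columns over all
alignment columns; `similarity_pct` additionally counts substitutions with
a positive matrix score — matching what the EBI output labels "similarity".
Tests compare scores against a recursive enumeration of complete
alignments: exhaustively for all pairs up to length 2 over a 4-letter
alphabet, and on seeded random pairs up to length 6 (global) / 5 (local) —
enumeration grows super-exponentially, so longer pairs are sampled rather
than exhausted.

The implementation is pure Python; for the pair sizes the pipeline aligns
(hundreds of residues) this is seconds per pair, which is adequate for a
34-pair family analysis but not for genome-scale all-vs-all searches.

## Duplication typing

A pair is **W** (segmental / whole-genome) when one duplicated-block pair
fully contains the two gene intervals on its two sides (either
orientation); partial overlap with a block does not count. Otherwise the
pair is **T** (tandem) when all three criteria hold: same chromosome with
at most 5 intervening gene loci (|locus-rank difference| − 1), inter-gene
distance ≤ 100 kb, and protein similarity ≥ 80 %. Everything else is **O**.
Three conventions are package choices where the source rules are silent:
W takes precedence over T; distance is the base-pair gap between the nearer
gene ends (0 for overlapping intervals); and locus rank is per-chromosome
order by start coordinate with ties broken by gene id. Blocks are an input
(as in the original analysis, which took them from the genome paper) —
de novo synteny detection is out of scope.

## Ka/Ks (NG86)

The estimator is Nei–Gojobori (1986) counting with Jukes–Cantor
correction, chosen as the standard simple method because the survey's
methods citation does not name an algorithm. The pipeline:

1. global protein alignment of the two translations (guide),
2. threading the guide back onto the in-frame CDSs; gap columns and codon
   pairs containing stops or ambiguous bases are dropped, never imputed,
3. site counting: each codon position contributes the fraction of its
   three single-nucleotide mutations that are synonymous, with mutations
   creating stop codons excluded from the denominator (so S + N = 3 ×
   codons always holds),
4. difference counting: codons differing at k positions are averaged over
   all k! single-step orderings with equal weight, excluding pathways that
   pass through a stop codon,
5. p<sub>S</sub> = S<sub>d</sub>/S and p<sub>N</sub> = N<sub>d</sub>/N,
   corrected as d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 yields an explicit
   *undefined* value (flagged, never a silent NaN), and the ratio is
   defined only when K<sub>s</sub> > 0.

Purifying selection is called at Ka/Ks < 0.5, the interpretation threshold
used for this family; the conventional neutrality threshold 1.0 is
available via the `threshold` argument. Two known NG86 edge behaviours are
documented rather than patched: on adversarial single codons (e.g.
AAA/AAG) stop exclusion can shrink S below S<sub>d</sub>, surfacing as an
undefined K<sub>s</sub>; and pathway averaging can attribute fractional
nonsynonymous differences to codons whose realized history was purely
synonymous, so a simulated ω = 0 yields a near-zero, not exactly zero, Ka.

## Expression analysis

Probe-level matrices are collapsed to genes by the median across a gene's
probe sets; genes sharing one probe set receive identical rows. Gene-wise
normalization is the per-row z-score with sample SD (n−1) — the original
clustering tool's exact convention is undocumented; constant rows become
zeros with a log entry. Clustering is agglomerative with average linkage
on d = 1 − Pearson r (scipy's implementation, checked in tests against a
naive agglomeration oracle that recomputes all distances each step).

"Expressed" has no published criterion, so the package defines it as a
normalized value above τ (default 0, i.e. above the gene's own mean);
every report records the τ used. The four paralog divergence categories
are pure set relations between the two expressed-tissue sets: 1 disjoint,
2 identical (two empty sets are flagged but still 2), 3 proper subset,
4 partial overlap. Highest-tissue calls take the row argmax with ties to
the first column (logged). RT-qPCR quantification is reference-gene
relative, 2^−ΔCt, since the protocol specifies a reference gene but no
calibrator sample. Log2 pre-transformation of raw values is available but
off by default because input scale varies by platform.

## Synthetic data generators

All generators are pure functions of (parameters, seed) using a single
`numpy` PCG64 stream; identical calls give identical outputs.

**Proteomes.** Background residues are drawn uniformly from the 20
standard amino acids minus C, H and L. Excluding C and H makes the planted
motif geometry the only one in the sequence, so motif truth is exact;
excluding L removes the mandatory leucine of the NES consensus, so no
unplanted NES can arise (planted-NES recall is then exactly measurable;
precision is not claimed, since a background V near a planted NES can
legitimately start a second overlapping match). Planted elements are
separated by at least one background residue. A full-alphabet `hard_mode`
exists for stress testing; its truth must be recomputed by the exhaustive
scanner. Real proteomes differ in composition, repeats and domain
structure — passing recovery tests shows the scanner's correctness, not
its behaviour on biased composition.

**Gene maps.** Chromosomes receive genes with 150–250 kb default
intergenic gaps (so unplanted neighbours never satisfy the 100-kb tandem
rule), tandem arrays with 5–60 kb gaps in the low locus ranks, homologous
block pairs over disjoint windows of the high ranks (so no gene belongs to
two planted pairs), and cross-chromosome O pairs in between.

**Codon pairs.** The simulator is a simple acceptance-thinning process —
uniform single-nucleotide proposals, stop-creating proposals rejected,
synonymous proposals accepted with probability 1 and nonsynonymous with
probability ω; the accepted-event count is Poisson with mean
(substitutions per codon) × codons. It is not a full codon model (no
transition/transversion bias, no codon frequencies) and is intended for
NG86 recovery checks, where the median estimated Ka/Ks over 200 replicates
of 300 codons at 0.2 substitutions/codon falls within ±20 % of ω for
ω ≤ 1.

**Expression matrices.** Each planted gene's row is +signal on its
expressed tissues and −signal elsewhere, plus Gaussian noise, with set
sizes bounded to 2…(labels−2). The bounds are part of the design: a
near-full or near-empty expressed set sits within signal/6 of the row
mean, where moderate noise corrupts the planted relation itself rather
than testing its recovery; the bounded sizes guarantee every label a
margin of at least 2/3 of a signal unit. Category recovery at noise
SD = 0.2 (signal 1.0) exceeds 0.95 over 200 pairs; pushing the noise to
the signal scale degrades recovery, which is expected behaviour, not a
defect.

## Bundled reference tables

Two TSVs transcribed from the published family survey ship with the
package: the 91-gene table and the 34-pair table. Desk audits run the
package's own summary operations on them: length extremes (96–2120 aa),
the fraction of proteins with ≥ 2 motifs (69.2 %), linkage-group
assignment from POPTR locus ids (90 of 91; the 4-digit chromosome field
0001–0019 maps to LG I–XIX, anything else to `scaffold_<n>`, a labelling
convention of this package), duplication-type counts (22 W / 2 T / 10 O),
and selection calls at 0.5 (3 pairs at or above). The table's internal
Ka/Ks arithmetic is audited to |Δ| ≤ 0.002 per row. The arithmetic mean
length of the printed column is 570.9 aa; the table's original running
text rounds this differently (579), so the computed mean is reported and
the discrepancy noted rather than reproduced.

The family's actual protein sequences are not redistributable with the
package, so sequence-level census figures (e.g. the NES census over the
real family) can only be recomputed against a locally provided FASTA; the
corresponding test states this requirement explicitly.

## Problem sizes and tolerances

Default verification sizes — 100–200 sequences for scanner/oracle
agreement, 200 × 300-codon replicates per ω for Ka/Ks recovery, 200
planted pairs for expression recovery, toy alphabets up to length 5–6 for
exhaustive alignment oracles — were chosen so the whole suite runs in well
under a minute while keeping Monte-Carlo standard errors far inside the
asserted bounds. Numerical tolerances: pI bisection to 1e-6 pH; floating
comparisons in tests at pytest defaults (rel 1e-6) except where a
published figure's printed precision dictates otherwise.
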