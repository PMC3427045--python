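"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the production code paths: the motif oracle
enumerates every (start, m, n, p) combination directly; the NES oracle uses
the ``re`` engine; the alignment oracle enumerates complete alignments
recursively and scores them after the fact; the clustering oracle is a
naive agglomeration recomputing all pairwise distances each step.
"""

from __future__ import annotations

import re
from itertools import combinations

import numpy as np


# -- CCCH motif oracle --------------------------------------------------------

def brute_force_matches(seq, m_range=(4, 15), n_range=(4, 6), p_range=(3, 3)):
    """Every (start, m, n, p) whose C/C/C/H geometry holds, by direct check."""
    out = []
    for start in range(len(seq)):
        for m in range(m_range[0], m_range[1] + 1):
            for n in range(n_range[0], n_range[1] + 1):
                for p in range(p_range[0], p_range[1] + 1):
                    idx = (start, start + m + 1, start + m + n + 2,
                           start + m + n + p + 3)
                    if idx[3] < len(seq) and (
                        seq[idx[0]] == "C" and seq[idx[1]] == "C"
                        and seq[idx[2]] == "C" and seq[idx[3]] == "H"
                    ):
                        out.append((start, m, n, p))
    return out


def brute_force_greedy(seq, m_range=(4, 15), n_range=(4, 6), p_range=(3, 3)):
    """Leftmost/smallest-span sweep over the exhaustive match list."""
    matches = brute_force_matches(seq, m_range, n_range, p_range)
    chosen = []
    cursor = 0
    while True:
        live = [t for t in matches if t[0] >= cursor]
        if not live:
            break
        start, m, n, p = min(
            live, key=lambda t: (t[0], t[1] + t[2] + t[3] + 4, t[1])
        )
        chosen.append((start, m, n, p))
        cursor = start + m + n + p + 4
    return chosen


# -- NES oracle ---------------------------------------------------------------

_NES_RE = re.compile(r"(?=([LV].{2,3}[LIVFM].{2,3}L.[LIMTKD]))")


def nes_starts_regex(seq):
    """Set of NES match-start positions, via the regex engine."""
    return {m.start() for m in _NES_RE.finditer(seq)}


# -- alignment oracle ---------------------------------------------------------

class ToyMatrix:
    """match/mismatch matrix with the Bio.Align [a, b] access convention."""

    def __init__(self, match=5.0, mismatch=-4.0):
        self.match, self.mismatch = match, mismatch

    def __getitem__(self, key):
        a, b = key
        return self.match if a == b else self.mismatch


def score_columns(cols, matrix, gap_open, gap_extend):
    """Score a column list [(ca, cb), ...] with affine gap runs
    (gap of length L costs open + (L-1)*extend, per row)."""
    score = 0.0
    run_a = run_b = 0
    for ca, cb in cols:
        if ca == "-":
            run_a += 1
            score -= gap_open if run_a == 1 else gap_extend
        else:
            run_a = 0
        if cb == "-":
            run_b += 1
            score -= gap_open if run_b == 1 else gap_extend
        else:
            run_b = 0
        if ca != "-" and cb != "-":
            score += float(matrix[ca, cb])
    return score


def enumerate_global(a, b, matrix, gap_open, gap_extend):
    """Optimal global score by enumerating every alignment recursively."""
    best = [float("-inf")]

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            s = score_columns(cols, matrix, gap_open, gap_extend)
            if s > best[0]:
                best[0] = s
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


def enumerate_local(a, b, matrix, gap_open, gap_extend):
    """Optimal local score: best global score over all substring pairs
    (an optimal local alignment is a global alignment of two substrings)."""
    best = 0.0
    for ia in range(len(a)):
        for ja in range(ia + 1, len(a) + 1):
            for ib in range(len(b)):
                for jb in range(ib + 1, len(b) + 1):
                    s = enumerate_global(
                        a[ia:ja], b[ib:jb], matrix, gap_open, gap_extend
                    )
                    if s > best:
                        best = s
    return best


# -- NG86 site oracle ---------------------------------------------------------

def ng86_sites_by_hand(codon, genetic_code, stops):
    """Synonymous sites of one codon by explicit mutation listing."""
    total = 0.0
    for pos in range(3):
        muts = [
            codon[:pos] + b + codon[pos + 1:]
            for b in "ACGT" if b != codon[pos]
        ]
        valid = [m for m in muts if m not in stops]
        if valid:
            total += sum(
                genetic_code[m] == genetic_code[codon] for m in valid
            ) / len(valid)
    return total


# -- average-linkage oracle ---------------------------------------------------

def naive_average_linkage(values):
    """UPGMA on d = 1 - Pearson r, recomputing distances every step.

    Returns a list of (members_i, members_j, height) with members as
    frozensets of original row indices, merged in order; the pair with the
    smallest distance wins, ties to the smallest cluster indices.
    """
    n = values.shape[0]
    corr = np.corrcoef(values)
    dist = {
        (i, j): 1.0 - corr[i, j] for i, j in combinations(range(n), 2)
    }
    clusters = {i: frozenset([i]) for i in range(n)}
    active = list(range(n))
    next_id = n
    merges = []
    cluster_dist = dict(dist)
    while len(active) > 1:
        best = min(
            ((i, j) for i, j in combinations(active, 2)),
            key=lambda ij: (cluster_dist[ij], ij),
        )
        i, j = best
        h = cluster_dist[(i, j)]
        merges.append((clusters[i], clusters[j], h))
        merged = clusters[i] | clusters[j]
        clusters[next_id] = merged
        active = [k for k in active if k not in (i, j)]
        for k in active:
            di = cluster_dist[tuple(sorted((i, k)))]
            dj = cluster_dist[tuple(sorted((j, k)))]
            wi, wj = len(clusters[i]), len(clusters[j])
            cluster_dist[(k, next_id)] = (wi * di + wj * dj) / (wi + wj)
        active.append(next_id)
        next_id += 1
    return merges
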