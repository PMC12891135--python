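"""Independent brute-force oracles used by the tests.

Everything here works by direct string scanning, pair counting, or full
enumeration — deliberately naive and separate from the library's vectorised
implementations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def end_motif_counts(fragments, sequences: dict[str, str], k: int) -> dict[str, int]:
    """Both 5'-end motifs per fragment by direct slicing; N/edge windows skipped."""
    counts: dict[str, int] = {}
    for chrom, start, end, _strand in fragments:
        seq = sequences[chrom]
        plus = seq[start : start + k]
        if len(plus) == k and "N" not in plus:
            counts[plus] = counts.get(plus, 0) + 1
        if end - k >= 0:
            minus = revcomp(seq[end - k : end])
            if len(minus) == k and "N" not in minus:
                counts[minus] = counts.get(minus, 0) + 1
    return counts


def breakpoint_motif_counts(fragments, sequences: dict[str, str], flank: int) -> dict[str, int]:
    """2*flank-mers straddling each 5' breakpoint, oriented per end strand."""
    k = 2 * flank
    counts: dict[str, int] = {}
    for chrom, start, end, _strand in fragments:
        seq = sequences[chrom]
        if start - flank >= 0:
            plus = seq[start - flank : start + flank]
            if len(plus) == k and "N" not in plus:
                counts[plus] = counts.get(plus, 0) + 1
        if end - flank >= 0:
            minus_win = seq[end - flank : end + flank]
            if len(minus_win) == k and "N" not in minus_win:
                minus = revcomp(minus_win)
                counts[minus] = counts.get(minus, 0) + 1
    return counts


def background_motif_counts(sequences: dict[str, str], k: int) -> dict[str, int]:
    """All windows of both strands by direct slicing."""
    counts: dict[str, int] = {}
    for seq in sequences.values():
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            counts[w] = counts.get(w, 0) + 1
            rc = revcomp(w)
            counts[rc] = counts.get(rc, 0) + 1
    return counts


def auc_concordant_pairs(scores, labels) -> float:
    """AUC as the concordant-pair probability with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def _u_statistic(x, y) -> float:
    """Mann-Whitney U of x over y (ties 1/2)."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def wilcoxon_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments
    (tie-free data): 2 * min(P(U <= u), P(U >= u)), capped at 1."""
    x = list(x)
    y = list(y)
    pooled = x + y
    n1 = len(x)
    u_obs = _u_statistic(x, y)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(_u_statistic(xs, ys))
    us = np.asarray(us)
    cdf = float((us <= u_obs + 1e-9).mean())
    sf = float((us >= u_obs - 1e-9).mean())
    return min(1.0, 2.0 * min(cdf, sf))


def bin_pass_bruteforce(seq: str, start: int, end: int, gc_min: float, blacklist) -> bool:
    """Recompute a bin's pass flag directly from the sequence and intervals."""
    window = seq[start:end]
    acgt = [c for c in window if c != "N"]
    if not acgt:
        return False
    gc = sum(1 for c in acgt if c in "GC") / len(acgt)
    if gc < gc_min:
        return False
    for s, e in blacklist:
        if s < end and e > start:
            return False
    return True


def midpoint_repeat_counts(fragments, intervals) -> dict[str, int]:
    """Per-subfamily midpoint containment by direct scan; nested intervals
    resolve to the smallest containing one."""
    counts: dict[str, int] = {}
    for chrom, start, end, _strand in fragments:
        mid = (start + end) // 2
        best = None
        best_size = None
        for c, s, e, name in intervals:
            if c == chrom and s <= mid < e:
                if best_size is None or e - s < best_size:
                    best, best_size = name, e - s
        if best is not None:
            counts[best] = counts.get(best, 0) + 1
    return counts
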