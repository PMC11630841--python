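"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: peak finding by direct
enumeration of local maxima plus a hand-rolled greedy filter, alignment by
exhaustive enumeration of the global alignment space, the signed-rank test by
enumeration of all sign assignments, and Pearson by the raw covariance
formula.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def enumerate_local_maxima(hist) -> list[int]:
    """0-based indices of strict local maxima; plateaus yield their midpoint
    (left sample on even-width plateaus).  Edges cannot be maxima."""
    hist = list(hist)
    n = len(hist)
    maxima = []
    i = 1
    while i < n - 1:
        if hist[i - 1] < hist[i]:
            j = i
            while j < n - 1 and hist[j + 1] == hist[i]:
                j += 1
            if j < n - 1 and hist[j + 1] < hist[i]:
                maxima.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return maxima


def brute_force_peaks(hist, min_height: float, min_distance: int) -> list[int]:
    """Enumerate-then-greedy-filter peak finding; returns sorted 0-based bins.

    Candidates below min_height are dropped; survivors are accepted greedily
    in order of descending height (ties: lower index first), discarding any
    candidate closer than min_distance bins to an accepted one.
    """
    hist = list(hist)
    candidates = [i for i in enumerate_local_maxima(hist)
                  if hist[i] >= min_height]
    order = sorted(candidates, key=lambda i: (-hist[i], i))
    accepted: list[int] = []
    for c in order:
        if all(abs(c - a) >= min_distance for a in accepted):
            accepted.append(c)
    return sorted(accepted)


def _pair_score(sa: str, sb: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Score an aligned pair: matrix for residue columns, affine cost per gap
    run (open for the first column, extend for each further column)."""
    score = 0.0
    prev_gap_a = prev_gap_b = False
    for x, y in zip(sa, sb):
        if x == "-":
            score += gap_extend if prev_gap_a else gap_open
            prev_gap_a, prev_gap_b = True, False
        elif y == "-":
            score += gap_extend if prev_gap_b else gap_open
            prev_gap_a, prev_gap_b = False, True
        else:
            score += matrix[x, y]
            prev_gap_a = prev_gap_b = False
    return score


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (aligned_a, aligned_b)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for sa, sb in enumerate_alignments(a[:-1], b):
            yield sa + a[-1], sb + "-"
    if b:
        for sa, sb in enumerate_alignments(a, b[:-1]):
            yield sa + "-", sb + b[-1]
    if a and b:
        for sa, sb in enumerate_alignments(a[:-1], b[:-1]):
            yield sa + a[-1], sb + b[-1]


def brute_force_align_score(
    a: str, b: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Optimal global alignment score by exhaustive enumeration."""
    return max(
        _pair_score(sa, sb, matrix, gap_open, gap_extend)
        for sa, sb in enumerate_alignments(a, b)
    )


def wilcoxon_enumeration_p(diffs, alternative: str = "greater") -> tuple[float, float]:
    """Exact one-sided signed-rank p by enumerating all 2^n sign assignments.

    Requires nonzero, untied |differences|.  Returns (W+, p)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = float(ranks[d > 0].sum())
    count = 0
    total = 2**n
    for signs in itertools.product((0, 1), repeat=n):
        w = float(sum(r for s, r in zip(signs, ranks) if s))
        if alternative == "greater":
            count += w >= w_obs
        else:
            count += w <= w_obs
    return w_obs, count / total


def pearson_direct(x, y) -> float:
    """Pearson r from the raw covariance / sigma-sigma formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    cov = float(((x - mx) * (y - my)).sum())
    return cov / math.sqrt(float(((x - mx) ** 2).sum()) * float(((y - my) ** 2).sum()))
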