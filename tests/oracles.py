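"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exact rational
hypergeometric enumeration for Fisher's test, regex scanning for MspI
digestion, exhaustive window scans for promoter classing, mid-rank Spearman,
and a naive agglomerative clustering that recomputes all pairwise
average-linkage distances at every step.
"""

from __future__ import annotations

import re
from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full hypergeometric enumeration.

    Sums P(X = x) over all tables with the observed margins whose point
    probability is <= the observed one (relative tolerance 1e-7 for ties),
    with all arithmetic in Fractions until the final float conversion.
    """
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, k)
    support = range(max(0, k - r2), min(r1, k) + 1)
    probs = [Fraction(comb(r1, x) * comb(r2, k - x), denom) for x in support]
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    cutoff = p_obs * (1 + Fraction(1, 10 ** 7))
    return float(sum(p for p in probs if p <= cutoff))


def fisher_pmf_table(r1: int, r2: int, k: int) -> dict[int, Fraction]:
    """Hypergeometric pmf over the support for margins (r1, r2) and k."""
    n = r1 + r2
    denom = comb(n, k)
    return {
        x: Fraction(comb(r1, x) * comb(r2, k - x), denom)
        for x in range(max(0, k - r2), min(r1, k) + 1)
    }


def mspi_fragments(seq: str) -> list[tuple[int, int]]:
    """Digest oracle: overlapping regex scan for CCGG, cut one base in."""
    cuts = [0] + [m.start() + 1 for m in re.finditer(r"(?=CCGG)", seq)] + [len(seq)]
    return [(s, e) for s, e in zip(cuts[:-1], cuts[1:]) if e > s]


def window_class(seq: str, window: int = 500, oe_high: float = 0.75,
                 oe_low: float = 0.48, gc_min: float = 0.55) -> str:
    """Promoter class by exhaustive every-offset (step=1) window scan."""
    w = min(window, len(seq))
    any_high, any_mid = False, False
    for o in range(0, len(seq) - w + 1):
        sub = seq[o:o + w]
        n_c, n_g = sub.count("C"), sub.count("G")
        n_cpg = sub.count("CG")
        oe = (n_cpg * w / (n_c * n_g)) if n_c and n_g else 0.0
        gc = (n_c + n_g) / w
        if oe >= oe_high and gc >= gc_min:
            any_high = True
        if oe >= oe_low:
            any_mid = True
    if any_high:
        return "HCP"
    if not any_mid:
        return "LCP"
    return "ICP"


def window_max_oe(seq: str, window: int = 500) -> float:
    """Maximum CpG O/E over every window offset (brute force)."""
    w = min(window, len(seq))
    best = 0.0
    for o in range(0, len(seq) - w + 1):
        sub = seq[o:o + w]
        n_c, n_g = sub.count("C"), sub.count("G")
        if n_c and n_g:
            best = max(best, sub.count("CG") * w / (n_c * n_g))
    return best


def midrank_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman as Pearson on mid-ranks, ranks computed by brute force."""
    def midranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def average_linkage_steps(points: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Naive UPGMA: at each step recompute all pairwise average distances.

    Returns the merge sequence as (cluster_a, cluster_b, height) with
    clusters given as frozensets of original row indices.
    """
    clusters: list[frozenset] = [frozenset([i]) for i in range(len(points))]
    pair_d = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i in range(len(points)) for j in range(i + 1, len(points))
    }

    def cdist(a: frozenset, b: frozenset) -> float:
        return float(np.mean([
            pair_d[(min(i, j), max(i, j))] for i in a for j in b
        ]))

    steps = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cdist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        steps.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return steps
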