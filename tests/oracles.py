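"""Independent brute-force / hand-formula oracles used by the test suite.

Each oracle recomputes a quantity from its mathematical definition using
plain loops and sets, deliberately avoiding the code paths (and where
possible the library calls) used by the implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist


def welch_oracle(a, b, alternative: str = "greater", equal_var: bool = False):
    """Two-sample t-test from the explicit formulas."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    if equal_var:
        vp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(vp * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = (m1 - m2) / se
    if alternative == "greater":
        p = t_dist.sf(t, df)
    elif alternative == "less":
        p = t_dist.cdf(t, df)
    else:
        p = 2 * t_dist.sf(abs(t), df)
    return t, float(p)


def bh_oracle(p_values):
    """Benjamini-Hochberg step-up by O(m^2) suffix minimization."""
    p = [float(x) for x in p_values]
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        adjusted[i] = min(1.0, min(candidates))
    return adjusted


def scale_factor_oracle(green_human, red_human) -> float:
    total_g = 0.0
    total_r = 0.0
    for g, r in zip(green_human, red_human, strict=True):
        total_g += float(g)
        total_r += float(r)
    return total_g / total_r


def normalize_oracle(g: float, r: float, sf: float, mode: str) -> float:
    if mode == "literal":
        return math.log2(g) - sf * math.log2(r)
    return math.log2(g) - math.log2(sf * r)


def ch_oracle(points, labels) -> float:
    """Calinski-Harabasz from its definition, pure-Python loops."""
    points = [list(map(float, row)) for row in np.atleast_2d(points)]
    labels = list(labels)
    n, d = len(points), len(points[0])
    clusters = sorted(set(labels))
    k = len(clusters)
    overall = [sum(row[j] for row in points) / n for j in range(d)]
    between = 0.0
    within = 0.0
    for c in clusters:
        members = [points[i] for i in range(n) if labels[i] == c]
        centroid = [sum(row[j] for row in members) / len(members) for j in range(d)]
        between += len(members) * sum((centroid[j] - overall[j]) ** 2 for j in range(d))
        within += sum(
            (row[j] - centroid[j]) ** 2 for row in members for j in range(d)
        )
    if within == 0.0:
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


def complete_linkage_heights_oracle(points) -> list[float]:
    """Merge heights of naive O(n^3) complete-linkage agglomeration."""
    points = [np.asarray(row, dtype=float) for row in np.atleast_2d(points)]
    clusters: list[list[int]] = [[i] for i in range(len(points))]

    def cluster_distance(a: list[int], b: list[int]) -> float:
        return max(
            float(np.sqrt(np.sum((points[i] - points[j]) ** 2))) for i in a for j in b
        )

    heights: list[float] = []
    while len(clusters) > 1:
        best = None
        best_pair = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cluster_distance(clusters[i], clusters[j])
                if best is None or d < best:
                    best, best_pair = d, (i, j)
        i, j = best_pair
        heights.append(best)
        merged = clusters[i] + clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    return heights


def union_prevalence_oracle(detected: dict[str, set[str]], group: list[str]) -> float:
    """Percent of group samples detected by at least one probe (set union)."""
    union: set[str] = set()
    for samples in detected.values():
        union |= samples
    return 100.0 * len(union & set(group)) / len(group)


def max_prevalence_oracle(detected: dict[str, set[str]], group: list[str]) -> float:
    """Percent from the best single probe's detected-sample count."""
    best = max((len(samples & set(group)) for samples in detected.values()), default=0)
    return 100.0 * best / len(group)
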