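"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own vectorized implementations:
the enrichment-score oracle walks the ranked list step by step, and the
clustering oracle agglomerates naively from the original distance matrix.
"""

from __future__ import annotations

import numpy as np


def brute_force_enrichment_score(
    ranked_scores: list[float],
    hit_positions: set[int],
    weight_exponent: float,
) -> float:
    """Step-by-step weighted KS running sum; returns the signed extreme.

    Positive extreme preferred when the two extremes tie in magnitude.
    """
    n_total = len(ranked_scores)
    n_hits = len(hit_positions)
    hit_weights = {
        p: abs(ranked_scores[p]) ** weight_exponent for p in hit_positions
    }
    total = sum(hit_weights.values())
    if total == 0:
        hit_weights = {p: 1.0 for p in hit_positions}
        total = float(n_hits)
    miss_step = 1.0 / (n_total - n_hits)
    running = 0.0
    best_pos, best_neg = -np.inf, np.inf
    for p in range(n_total):
        if p in hit_positions:
            running += hit_weights[p] / total
        else:
            running -= miss_step
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    return best_pos if best_pos >= -best_neg else best_neg


def naive_agglomerate(
    dist: np.ndarray, linkage: str
) -> tuple[list[float], list[frozenset[int]]]:
    """O(n^3) agglomerative clustering from the original distance matrix.

    Returns merge heights and internal-node leafsets (as index sets), in
    merge order.  Cluster-to-cluster distance is computed directly from
    the original matrix: mean over member pairs for average linkage, max
    for complete linkage.  Ties pick the first pair in index order.
    """
    n = dist.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    heights: list[float] = []
    leafsets: list[frozenset[int]] = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                pair_d = [
                    dist[i, j] for i in clusters[a] for j in clusters[b]
                ]
                d = max(pair_d) if linkage == "complete" else float(np.mean(pair_d))
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        new_id = n + len(heights)
        clusters[new_id] = merged
        heights.append(d)
        leafsets.append(merged)
    return heights, leafsets
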