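"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately naive re-derivation of a quantity the package
computes through a different route (vectorized code or a library call), so
agreement is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by literal step-up.

    Sort p-values, scale p_(i) by n/i, then enforce monotonicity by a
    cumulative minimum from the largest rank downwards; cap at 1.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adj[i] = running_min
    return adj


def auc_concordance(scores, truth) -> float:
    """AUC as pairwise concordance over all positive-negative pairs,
    ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def ward_linkage_exhaustive(X: np.ndarray) -> np.ndarray:
    """Ward agglomeration by explicit greedy merging (ward.D2 convention).

    At each step, merge the pair of clusters with the smallest Ward distance
    d(A, B) = sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B||,
    recomputed from scratch from cluster members each step.  Returns a
    scipy-style (n-1) x 4 linkage matrix.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    Z = []

    def ward_dist(a: list[int], b: list[int]) -> float:
        ca, cb = X[a].mean(axis=0), X[b].mean(axis=0)
        na, nb = len(a), len(b)
        return float(
            np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
        )

    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = ward_dist(clusters[i], clusters[j])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        merged = clusters.pop(i) + clusters.pop(j)
        Z.append([i, j, d, len(merged)])
        clusters[next_id] = merged
        next_id += 1
    return np.array(Z)


def combat_two_batch_location(X: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Location-only two-batch adjustment, no shrinkage, no covariate.

    For each gene, subtract each batch's own mean and add back the weighted
    grand mean.  The closed form any location-scale batch adjustment must
    reduce to when scale effects are absent and priors are flat.
    """
    X = np.asarray(X, dtype=float).copy()
    batch = np.asarray(batch)
    grand = X.mean(axis=1, keepdims=True)
    for b in np.unique(batch):
        cols = batch == b
        X[:, cols] = X[:, cols] - X[:, cols].mean(axis=1, keepdims=True) + grand
    return X
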