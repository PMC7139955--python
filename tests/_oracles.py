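"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: the clustering
oracle rescans every pairwise centroid distance from scratch at every
step with scipy's pearsonr, and the Cox oracle maximizes an explicitly
written partial likelihood by scalar optimization.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize, stats


def brute_force_centroid_merges(
    profiles: np.ndarray, labels: list[str]
) -> list[tuple[frozenset[str], frozenset[str], float]]:
    """O(n^3) centroid-correlation agglomeration: at every step rescan
    all cluster pairs, recomputing centroids from the raw profiles.

    Ties in minimum distance break on the lexicographically smallest
    pair of smallest member labels; inversions are flattened to the
    previous height.  Returns (left members, right members, height).
    """
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(labels))}
    next_id = len(labels)
    merges = []
    last_h = -math.inf
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ca = profiles[clusters[a]].mean(axis=0)
            cb = profiles[clusters[b]].mean(axis=0)
            d = 1.0 - stats.pearsonr(ca, cb).statistic
            rep = tuple(
                sorted(
                    (
                        min(labels[i] for i in clusters[a]),
                        min(labels[i] for i in clusters[b]),
                    )
                )
            )
            key = (round(d, 12), rep)
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        h = max(d, last_h)
        last_h = h
        merges.append(
            (
                frozenset(labels[i] for i in clusters[a]),
                frozenset(labels[i] for i in clusters[b]),
                h,
            )
        )
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def cox_partial_loglik_1d(
    beta: float, x: np.ndarray, t: np.ndarray, e: np.ndarray, ties: str
) -> float:
    """Explicit one-covariate Cox log partial likelihood.

    Breslow: every tied event shares the full risk-set denominator.
    Efron: the l-th of d tied events subtracts l/d of the tied group's
    own hazard from the denominator.
    """
    ll = 0.0
    for tt in np.unique(t[e == 1]):
        events = np.where((t == tt) & (e == 1))[0]
        risk = np.where(t >= tt)[0]
        d = len(events)
        s0 = np.exp(beta * x[risk]).sum()
        ll += beta * x[events].sum()
        if ties == "breslow":
            ll -= d * math.log(s0)
        else:
            t0 = np.exp(beta * x[events]).sum()
            for l in range(d):
                ll -= math.log(s0 - (l / d) * t0)
    return ll


def cox_mle_1d(x: np.ndarray, t: np.ndarray, e: np.ndarray, ties: str) -> float:
    """Scalar-optimization MLE of the one-covariate partial likelihood."""
    res = optimize.minimize_scalar(
        lambda b: -cox_partial_loglik_1d(b, x, t, e, ties),
        bounds=(-20.0, 20.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
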