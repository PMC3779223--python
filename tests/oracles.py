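"""Independent oracles for cross-checking the implementation.

Everything here is deliberately written without importing the code paths
it checks: superposition oracles go through scipy's rotation machinery and
direct numerical search, aggregation oracles are naive double loops, and
the Wang oracle enumerates root-ward paths explicitly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def scipy_kabsch(X: np.ndarray, Y: np.ndarray):
    """Optimal superposition of Y onto X via scipy's align_vectors."""
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    R, _ = Rotation.align_vectors(X - cx, Y - cy)
    mapped = R.apply(Y - cy) + cx
    rmsd = float(np.sqrt(np.mean(np.sum((mapped - X) ** 2, axis=1))))
    return R, mapped, rmsd


def brute_force_rmsd(X: np.ndarray, Y: np.ndarray, rng: np.random.Generator,
                     n_starts: int = 60) -> float:
    """Minimum RMSD over rotations by multi-start local refinement.

    Rotations are parameterized by rotation vectors; starts are drawn
    uniformly from the rotation group plus the identity.  Translation is
    eliminated by centering (optimal for any fixed rotation).
    """
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    n = len(X)

    def cost(rotvec: np.ndarray) -> float:
        mapped = Rotation.from_rotvec(rotvec).apply(Yc)
        return float(np.sum((mapped - Xc) ** 2))

    starts = [np.zeros(3)] + [r.as_rotvec() for r in
                              Rotation.random(n_starts, random_state=rng)]
    best = np.inf
    for s in starts:
        res = minimize(cost, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 2000})
        best = min(best, res.fun)
    return math.sqrt(best / n)


def _tm_of_transform(R: Rotation, t: np.ndarray, Xa: np.ndarray,
                     Xb: np.ndarray, d0: float, L_N: int) -> float:
    d = np.linalg.norm(R.apply(Xb) + t - Xa, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_N)


def exhaustive_tm(Xa: np.ndarray, Xb: np.ndarray, d0: float,
                  L_N: int) -> float:
    """TM-score maximized over every contiguous seed fragment (length >= 4)
    with the same iterative close-pair refinement the published procedure
    prescribes, implemented on scipy rotations."""
    n = len(Xa)
    best = -np.inf
    for start, length in itertools.product(range(n), range(4, n + 1)):
        if start + length > n:
            continue
        idx = np.arange(start, start + length)
        ca = Xa[idx].mean(axis=0)
        cb = Xb[idx].mean(axis=0)
        R, _ = Rotation.align_vectors(Xa[idx] - ca, Xb[idx] - cb)
        t = ca - R.apply(cb)
        prev = -np.inf
        for _ in range(20):
            score = _tm_of_transform(R, t, Xa, Xb, d0, L_N)
            best = max(best, score)
            if score - prev < 1e-6:
                break
            prev = score
            d = np.linalg.norm(R.apply(Xb) + t - Xa, axis=1)
            sel = np.flatnonzero(d < d0 + 1.0)
            if sel.size < 4:
                sel = np.argsort(d)[:4]
            ca = Xa[sel].mean(axis=0)
            cb = Xb[sel].mean(axis=0)
            R, _ = Rotation.align_vectors(Xa[sel] - ca, Xb[sel] - cb)
            t = ca - R.apply(cb)
        best = max(best, _tm_of_transform(R, t, Xa, Xb, d0, L_N))
    return min(best, 1.0)


def naive_mean_rmsd(matrix: np.ndarray, index: int) -> float:
    vals = []
    for j in range(matrix.shape[1]):
        if j != index and not math.isnan(matrix[index, j]):
            vals.append(matrix[index, j])
    return sum(vals) / len(vals)


def naive_pair_rmsd(row_a, row_b, coords_a, coords_b, gap=-1) -> float:
    """Re-extract matched coordinates per pair from scratch and average."""
    sq = []
    for ca, cb in zip(row_a, row_b):
        if ca != gap and cb != gap:
            diff = coords_a[ca] - coords_b[cb]
            sq.append(float(diff @ diff))
    return math.sqrt(sum(sq) / len(sq))


def wang_svalues_by_paths(term: str, parents, weights) -> dict[str, float]:
    """S-values by explicit enumeration of all root-ward paths.

    *parents* maps term -> list of (parent, edge_type); *weights* maps
    edge_type -> factor.  S(u) is the max over all paths term -> u of the
    product of edge factors along the path.
    """
    S = {term: 1.0}
    stack = [(term, 1.0)]
    while stack:
        node, val = stack.pop()
        for parent, rel in parents.get(node, []):
            v = val * weights[rel]
            if v > S.get(parent, -1.0):
                S[parent] = v
            stack.append((parent, v))
    return S


def wang_term_similarity_naive(t1, t2, parents, weights) -> float:
    S1 = wang_svalues_by_paths(t1, parents, weights)
    S2 = wang_svalues_by_paths(t2, parents, weights)
    common = sorted(set(S1) & set(S2))
    if not common:
        return 0.0
    return (sum(S1[u] + S2[u] for u in common)
            / (sum(S1.values()) + sum(S2.values())))
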