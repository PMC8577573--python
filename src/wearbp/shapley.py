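"""Exact interventional Shapley values for tree ensembles.

For a decision tree, the prediction restricted to a feature coalition S —
features in S read from the explained sample x, the rest from a background
sample z — is a sum over leaves reached under the mixed input.  A leaf is
reached iff every feature constraint on its path is met by x (for features
in S) or by z (for features outside S).  Grouping the distinct path features
of a leaf into

* N: features where x satisfies the path constraints but z does not
  (must be *in* S for the leaf to be reached),
* D: features where z satisfies them but x does not (must be *out*),

the coalition game contributed by that leaf is ``v * [S >= N and S.isdisjoint(D)]``,
whose Shapley values have the closed form

    phi_i = +v / (n * C(n+d, n))   for i in N,
    phi_i = -v / (d * C(n+d, d))   for i in D,      n = |N|, d = |D|,

and 0 elsewhere (leaves where some path feature is satisfied by neither x
nor z are never reached).  Summing over leaves, trees, and a background
sample gives the exact Shapley attribution of ``f(x) - E_z[f(z)]`` under
marginal (interventional) expectations — identical to brute-force
enumeration of feature subsets, but in polynomial time.

The per-leaf accumulation is JIT-compiled; explained rows and background
rows sharing a pass/fail bit pattern at a leaf are deduplicated first.
"""

from __future__ import annotations

from math import comb, factorial
from itertools import combinations

import numpy as np
from numba import njit

_MAX_PATH_FEATURES = 64


def _weight_tables(m: int) -> tuple[np.ndarray, np.ndarray]:
    wpos = np.zeros((m + 1, m + 1))
    wneg = np.zeros((m + 1, m + 1))
    for n in range(m + 1):
        for d in range(m + 1 - n):
            if n:
                wpos[n, d] = 1.0 / (n * comb(n + d, n))
            if d:
                wneg[n, d] = 1.0 / (d * comb(n + d, d))
    return wpos, wneg


def _leaf_regions(tree) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flattened per-leaf path constraints of one fitted sklearn tree.

    Returns (values, leaf_ptr, path_feature, path_lo, path_hi): leaf l owns
    entries leaf_ptr[l]:leaf_ptr[l+1]; a sample passes entry t iff
    lo < sample[feature] <= hi.
    """
    cl, cr = tree.children_left, tree.children_right
    feat, thr = tree.feature, tree.threshold
    node_value = tree.value[:, 0, 0]

    values, ptr, pf, plo, phi_ = [], [0], [], [], []
    stack: list[tuple[int, dict]] = [(0, {})]
    while stack:
        node, bounds = stack.pop()
        if cl[node] == -1:
            values.append(node_value[node])
            for f, (lo, hi) in sorted(bounds.items()):
                pf.append(f)
                plo.append(lo)
                phi_.append(hi)
            ptr.append(len(pf))
            continue
        f, t = int(feat[node]), float(thr[node])
        lo, hi = bounds.get(f, (-np.inf, np.inf))
        left = dict(bounds)
        left[f] = (lo, min(hi, t))
        right = dict(bounds)
        right[f] = (max(lo, t), hi)
        stack.append((cl[node], left))
        stack.append((cr[node], right))
    if max(np.diff(ptr), default=0) > _MAX_PATH_FEATURES:
        raise ValueError("tree path uses more than 64 distinct features")
    return (
        np.asarray(values, dtype=np.float64),
        np.asarray(ptr, dtype=np.int64),
        np.asarray(pf, dtype=np.int64),
        np.asarray(plo, dtype=np.float64),
        np.asarray(phi_, dtype=np.float64),
    )


def _pack_masks(M: np.ndarray, pf, plo, phi_, ptr) -> np.ndarray:
    """Per-leaf pass bitmasks for the rows of M (rows x leaves, uint64)."""
    passes = (M[:, pf] > plo) & (M[:, pf] <= phi_)
    bitpos = np.arange(len(pf)) - ptr[:-1].repeat(np.diff(ptr))
    weighted = passes.astype(np.uint64) << bitpos.astype(np.uint64)
    if len(pf) == 0:
        return np.zeros((M.shape[0], len(ptr) - 1), dtype=np.uint64)
    out = np.add.reduceat(weighted, ptr[:-1].clip(max=len(pf) - 1), axis=1)
    out[:, np.diff(ptr) == 0] = 0
    return np.ascontiguousarray(out)


@njit(cache=True)
def _accumulate_tree(phi, values, ptr, pf, xmask, zmask, wpos, wneg):  # pragma: no cover
    L = values.shape[0]
    J = xmask.shape[0]
    B = zmask.shape[0]
    for leaf in range(L):
        start = ptr[leaf]
        p = ptr[leaf + 1] - start
        if p == 0:
            continue
        full = (np.uint64(1) << np.uint64(p)) - np.uint64(1)
        v = values[leaf]

        zs = np.sort(zmask[:, leaf])
        xorder = np.argsort(xmask[:, leaf], kind="mergesort")
        contrib = np.empty(p)

        i = 0
        while i < J:
            xm = xmask[xorder[i], leaf]
            gend = i + 1
            while gend < J and xmask[xorder[gend], leaf] == xm:
                gend += 1
            for t in range(p):
                contrib[t] = 0.0
            k = 0
            while k < B:
                zm = zs[k]
                run = k + 1
                while run < B and zs[run] == zm:
                    run += 1
                c = float(run - k)
                k = run
                if (xm | zm) != full:
                    continue  # some path feature fails for both x and z
                nm = xm & ~zm
                dm = zm & ~xm
                n = 0
                d = 0
                for t in range(p):
                    bit = (np.uint64(1) << np.uint64(t))
                    if nm & bit:
                        n += 1
                    elif dm & bit:
                        d += 1
                if n == 0 and d == 0:
                    continue  # leaf reached by both: baseline only
                for t in range(p):
                    bit = (np.uint64(1) << np.uint64(t))
                    if nm & bit:
                        contrib[t] += c * v * wpos[n, d]
                    elif dm & bit:
                        contrib[t] -= c * v * wneg[n, d]
            for g in range(i, gend):
                j = xorder[g]
                for t in range(p):
                    phi[j, pf[start + t]] += contrib[t]
            i = gend


def tree_shap_interventional(
    forest, X: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley matrix for a fitted tree ensemble.

    Returns ``(phi, baseline)`` with ``phi`` of shape (len(X), n_features)
    and ``baseline`` the mean prediction over the background sample, so that
    ``baseline + phi.sum(1) == forest.predict(X)`` (efficiency) holds to
    floating-point accuracy.
    """
    # sklearn trees compare float32-cast inputs against float64 thresholds;
    # rounding through float32 reproduces the traversal bit-exactly
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float32).astype(np.float64))
    Z = np.ascontiguousarray(np.asarray(background, dtype=np.float32).astype(np.float64))
    if Z.shape[0] == 0:
        raise ValueError("background sample is empty")
    estimators = getattr(forest, "estimators_", [forest])
    scale = 1.0 / len(estimators)
    phi = np.zeros((X.shape[0], X.shape[1]))
    wpos, wneg = _weight_tables(_MAX_PATH_FEATURES)
    for est in estimators:
        tree = est.tree_
        values, ptr, pf, plo, phi_hi = _leaf_regions(tree)
        xmask = _pack_masks(X, pf, plo, phi_hi, ptr)
        zmask = _pack_masks(Z, pf, plo, phi_hi, ptr)
        _accumulate_tree(phi, values * scale, ptr, pf, xmask, zmask, wpos, wneg)
    phi /= Z.shape[0]
    baseline = float(np.mean(forest.predict(Z)))
    return phi, baseline


def shapley_brute_force(predict, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Shapley values by explicit enumeration over all feature subsets.

    ``f(S)`` is the marginal expectation over the background sample: features
    in S are taken from the explained row, the rest from each background row,
    and predictions are averaged.  Exponential in the number of features —
    this is the independent test oracle, not the production path.
    """
    X = np.asarray(X, dtype=np.float64)
    Z = np.asarray(background, dtype=np.float64)
    J, K = X.shape
    if K > 16:
        raise ValueError("brute force limited to <= 16 features")

    f_cache: dict[frozenset, np.ndarray] = {}

    def f(S: frozenset) -> np.ndarray:
        if S not in f_cache:
            idx = sorted(S)
            mixed = np.repeat(Z[None, :, :], J, axis=0)  # (J, B, K)
            mixed[:, :, idx] = X[:, idx][:, None, :]
            preds = predict(mixed.reshape(-1, K)).reshape(J, -1)
            f_cache[S] = preds.mean(axis=1)
        return f_cache[S]

    phi = np.zeros((J, K))
    for k in range(K):
        others = [i for i in range(K) if i != k]
        for size in range(K):
            w = factorial(size) * factorial(K - size - 1) / factorial(K)
            for S in combinations(others, size):
                S = frozenset(S)
                phi[:, k] += w * (f(S | {k}) - f(S))
    return phi
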