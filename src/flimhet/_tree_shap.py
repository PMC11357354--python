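"""Exact Shapley attributions for sklearn tree ensembles on small feature sets.

For a tree, the path-dependent conditional expectation given a feature
coalition S is

    E[f(x) | x_S] = sum_leaves value_l * prod_{splits on path}
                        { 1[x satisfies split]   if split feature in S
                        { n_child / n_parent     otherwise

Because repeated splits on one feature along a path intersect to an interval,
each leaf reduces to, per feature: an interval [lo, hi) and a "cover
fraction" (product of the child/parent sample fractions of the path's splits
on that feature).  The coalition value is then a product over features of
either the interval indicator (feature in S) or the cover fraction (feature
out of S) — fully vectorizable over leaves and samples.

With M <= ~12 features, all 2^M coalitions are enumerated, giving *exact*
Shapley values (the quantity TreeSHAP approximates recursively) in both the
path-dependent and the interventional (background-marginalized) flavor.
"""

from __future__ import annotations

from math import factorial

import numpy as np

__all__ = ["forest_shapley"]


def _leaf_decomposition(tree, n_features: int):
    """Per-leaf (value, lo, hi, frac) arrays for one fitted sklearn tree."""
    t = tree.tree_
    leaves, los, his, fracs = [], [], [], []

    def descend(node: int, lo: np.ndarray, hi: np.ndarray, frac: np.ndarray) -> None:
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            value = t.value[node][0]
            total = value.sum()
            # class-1 probability for classifiers; raw value for regressors
            leaves.append(value[1] / total if len(value) > 1 else value[0])
            los.append(lo.copy())
            his.append(hi.copy())
            fracs.append(frac.copy())
            return
        f, thr = t.feature[node], t.threshold[node]
        w = t.weighted_n_node_samples
        for child, is_left in ((left, True), (right, False)):
            lo2, hi2, fr2 = lo.copy(), hi.copy(), frac.copy()
            if is_left:
                hi2[f] = min(hi2[f], thr)
            else:
                lo2[f] = max(lo2[f], thr)
            fr2[f] *= w[child] / w[node]
            descend(child, lo2, hi2, fr2)

    descend(
        0,
        np.full(n_features, -np.inf),
        np.full(n_features, np.inf),
        np.ones(n_features),
    )
    return (
        np.array(leaves),
        np.array(los),
        np.array(his),
        np.array(fracs),
    )


def forest_shapley(
    forest,
    X: np.ndarray,
    mode: str = "path",
    background: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Shapley values for each row of X under a fitted sklearn forest.

    Returns ``(phi, base)`` where ``phi`` has shape (n_samples, n_features),
    ``base`` (n_samples,) is the empty-coalition expectation, and
    ``phi.sum(axis=1) + base`` equals the model's class-1 probability.

    mode 'path' uses the tree's own training cover fractions (path-dependent);
    mode 'interventional' marginalizes absent features over ``background``
    rows jointly.
    """
    X = np.asarray(X, dtype=float)
    n, M = X.shape
    if M > 16:
        raise ValueError("exact coalition enumeration is limited to <= 16 features")
    if mode not in ("path", "interventional"):
        raise ValueError(f"unknown shap mode {mode!r}")
    if mode == "interventional":
        if background is None:
            background = X
        background = np.asarray(background, dtype=float)

    values_l, lo_l, hi_l, frac_l = [], [], [], []
    for est in forest.estimators_:
        v, lo, hi, fr = _leaf_decomposition(est, M)
        values_l.append(v)
        lo_l.append(lo)
        hi_l.append(hi)
        frac_l.append(fr)
    values = np.concatenate(values_l) / len(forest.estimators_)
    lo = np.concatenate(lo_l)
    hi = np.concatenate(hi_l)
    frac = np.concatenate(frac_l)

    # sklearn routes x <= threshold left, so leaf membership is lo < x <= hi
    ind = (X[:, None, :] > lo[None, :, :]) & (X[:, None, :] <= hi[None, :, :])
    if mode == "interventional":
        ind_bg = (background[:, None, :] > lo[None, :, :]) & (
            background[:, None, :] <= hi[None, :, :]
        )

    n_subsets = 1 << M
    v_of = np.empty((n_subsets, n))
    for mask in range(n_subsets):
        in_S = [f for f in range(M) if mask >> f & 1]
        out_S = [f for f in range(M) if not mask >> f & 1]
        w_in = ind[:, :, in_S].all(axis=2) if in_S else np.ones((n, ind.shape[1]), bool)
        if mode == "path":
            w_out = frac[:, out_S].prod(axis=1) if out_S else np.ones(ind.shape[1])
        else:
            w_out = (
                ind_bg[:, :, out_S].all(axis=2).mean(axis=0)
                if out_S
                else np.ones(ind.shape[1])
            )
        v_of[mask] = (w_in * w_out[None, :]) @ values

    phi = np.zeros((n, M))
    fact = [factorial(k) for k in range(M + 1)]
    for mask in range(n_subsets):
        s = bin(mask).count("1")
        for f in range(M):
            if mask >> f & 1:
                continue
            weight = fact[s] * fact[M - s - 1] / fact[M]
            phi[:, f] += weight * (v_of[mask | (1 << f)] - v_of[mask])
    return phi, v_of[0]
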