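"""Independent reference implementations used only to check the package.

Everything here is deliberately written against the definitions (double
loops, enumeration, exact covariance synthesis, permutation), not against
the package's vectorized code paths.
"""
from __future__ import annotations

import itertools

import numpy as np


def cholesky_fbm(n: int, hurst: float, seed: int, cache: dict | None = None) -> np.ndarray:
    """Exact fractional-Brownian surface on an n x n grid by Cholesky
    factorization of the fBm covariance C(p, q) = (|p|^2H + |q|^2H -
    |p-q|^2H)/2 with B(0) = 0 pinned off-grid.

    Exact by construction: the sampled field's variogram is sigma^2 d^2H
    in expectation at every integer lag, with no discretization bias.
    """
    key = (n, hurst)
    if cache is not None and key in cache:
        L = cache[key]
    else:
        ys, xs = np.mgrid[1 : n + 1, 1 : n + 1]
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        r = np.linalg.norm(pts, axis=1)
        diff = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        h2 = 2.0 * hurst
        C = 0.5 * (r[:, None] ** h2 + r[None, :] ** h2 - diff**h2)
        L = np.linalg.cholesky(C + 1e-9 * np.eye(len(C)))
        if cache is not None:
            cache[key] = L
    rng = np.random.default_rng(seed)
    return (L @ rng.standard_normal(L.shape[0])).reshape(n, n)


def brute_force_variogram(block: np.ndarray, direction: str, max_lag: int) -> np.ndarray:
    """O(rows * cols * lag) double-loop mean squared increment."""
    block = np.asarray(block, dtype=float)
    if direction in ("h", "horizontal"):
        arr = block
    else:
        arr = block.T
    rows, cols = arr.shape
    out = np.zeros(max_lag)
    for lag in range(1, max_lag + 1):
        acc, cnt = 0.0, 0
        for i in range(rows):
            for j in range(cols - lag):
                d = arr[i, j + lag] - arr[i, j]
                acc += d * d
                cnt += 1
        out[lag - 1] = acc / cnt
    return out


def variogram_slope(field: np.ndarray, lags) -> float:
    """log2-log2 OLS slope of the two directional variograms, averaged."""
    slopes = []
    for arr in (field, field.T):
        v = [np.mean((arr[:, d:] - arr[:, :-d]) ** 2) for d in lags]
        s, _ = np.polyfit(np.log2(lags), np.log2(v), 1)
        slopes.append(s)
    return float(np.mean(slopes))


def auc_pair_counting(labels, scores) -> float:
    """O(n^2) Mann-Whitney AUC: wins count 1, ties 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def permutation_p_paired_auc(labels, scores_a, scores_b, n_perm: int = 10000,
                             seed: int = 0) -> float:
    """Permutation p-value for a paired AUC difference: under the null the
    model assignment is exchangeable per knee, so each draw swaps the two
    scores of a random subset of knees."""
    labels = np.asarray(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    obs = abs(auc_pair_counting(labels, a) - auc_pair_counting(labels, b))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(labels.size) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        d = abs(_auc_fast(labels, pa) - _auc_fast(labels, pb))
        if d >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def _auc_fast(labels, scores) -> float:
    from scipy.stats import rankdata

    r = rankdata(scores)
    n1 = int((labels == 1).sum())
    n0 = labels.size - n1
    return (r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _aic_logit(y: np.ndarray, X: np.ndarray) -> float:
    """AIC of a logistic fit, straight from statsmodels (independent of
    the package's fitting wrapper)."""
    import statsmodels.api as sm

    design = sm.add_constant(X, has_constant="add")
    res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    return float(res.aic)


def exhaustive_backward_aic(table, forced, candidates, outcome="outcome"):
    """Best-AIC subset among backward-reachable subsets, by enumeration.

    A subset is backward-reachable when a chain of single-candidate drops
    from the full set reaches it with strictly decreasing AIC at every
    accepted step and a terminal state where no drop improves AIC further;
    the greedy minimum-AIC walk realises one such chain.  This enumerates
    the greedy walk over all 2^k subset AICs computed independently.
    """
    sub = table[[outcome] + forced + list(candidates)].dropna()
    y = sub[outcome].to_numpy(dtype=float)

    aic_cache = {}

    def aic_of(subset: frozenset) -> float:
        if subset not in aic_cache:
            cols = forced + sorted(subset)
            X = sub[cols].to_numpy(dtype=float) if cols else np.empty((len(y), 0))
            aic_cache[subset] = _aic_logit(y, X)
        return aic_cache[subset]

    current = frozenset(candidates)
    current_aic = aic_of(current)
    while current:
        options = sorted(current)
        best_name, best_aic = None, np.inf
        for name in options:
            a = aic_of(current - {name})
            if a < best_aic:
                best_name, best_aic = name, a
        if best_aic < current_aic:
            current = current - {best_name}
            current_aic = best_aic
        else:
            break
    return sorted(current), current_aic


def all_subset_aics(table, forced, candidates, outcome="outcome"):
    """AIC of every candidate subset (for k small)."""
    sub = table[[outcome] + forced + list(candidates)].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    out = {}
    for k in range(len(candidates) + 1):
        for combo in itertools.combinations(sorted(candidates), k):
            cols = forced + list(combo)
            X = sub[cols].to_numpy(dtype=float) if cols else np.empty((len(y), 0))
            out[frozenset(combo)] = _aic_logit(y, X)
    return out
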