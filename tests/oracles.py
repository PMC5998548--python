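"""Independent brute-force reference implementations for the oracle suites.

Everything here is written as plain nested loops over cells, with
scipy.stats.pearsonr for correlations and explicit normal equations for
regressions — deliberately naive, sharing no code path with the package
implementations they check.
"""

import numpy as np
from scipy import stats


def column_stat_fill(values: np.ndarray, stat) -> np.ndarray:
    out = values.copy()
    for j in range(values.shape[1]):
        col = [v for v in values[:, j] if not np.isnan(v)]
        fill = stat(col)
        for i in range(values.shape[0]):
            if np.isnan(out[i, j]):
                out[i, j] = fill
    return out


def pairwise_pearson(x: np.ndarray, y: np.ndarray, min_obs: int = 3) -> float:
    """Pearson r over pairwise-complete entries; NaN when undefined."""
    keep = [t for t in range(len(x)) if not np.isnan(x[t]) and not np.isnan(y[t])]
    if len(keep) < min_obs:
        return np.nan
    xs, ys = x[keep], y[keep]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return np.nan
    # 12-decimal rounding: analytic ties must not be ordered by fp noise
    return round(stats.pearsonr(xs, ys).statistic, 12)


def knn_fill(values: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive per-cell neighbour search; ties prefer the lower index."""
    n, m = values.shape
    out = values.copy()
    for i in range(n):
        for j in range(m):
            if not np.isnan(values[i, j]):
                continue
            candidates = []
            for other in range(n):
                if other == i or np.isnan(values[other, j]):
                    continue
                r = pairwise_pearson(values[i], values[other])
                if not np.isnan(r):
                    candidates.append((-r, other))
            if len(candidates) < k:
                out[i, j] = 0.0
            else:
                candidates.sort()
                chosen = [other for _, other in candidates[:k]]
                out[i, j] = np.mean([values[other, j] for other in chosen])
    return out


def lls_fill(values: np.ndarray, k: int = 2, tol: float = 0.001,
             max_iter: int = 100, max_condition: float = 1e8) -> np.ndarray:
    """Naive local least squares: normal equations, loops everywhere.

    Predictor assays are chosen once by |Pearson r| on the mean-filled
    matrix (lower index wins ties); ill-conditioned systems fall back to
    the column mean for that iteration; a non-convergent iteration
    yields the first (single-pass) iterate.
    """
    miss = np.isnan(values)
    current = column_stat_fill(values, np.mean)
    if not miss.any():
        return current
    n, m = values.shape
    col_mean = {j: np.nanmean(values[:, j]) for j in range(m)}

    preds_of = {}
    for j in range(m):
        if not miss[:, j].any():
            continue
        scores = []
        for other in range(m):
            if other == j:
                continue
            with np.errstate(invalid="ignore"):
                if np.std(current[:, other]) == 0 or np.std(current[:, j]) == 0:
                    score = -1.0  # undefined, sorts after every defined |r|
                else:
                    r = stats.pearsonr(current[:, other], current[:, j]).statistic
                    score = round(abs(r), 12) if np.isfinite(r) else -1.0
            scores.append((-score, other))
        scores.sort()
        preds_of[j] = [other for _, other in scores[:k]]

    first_iterate = None
    for iteration in range(max_iter):
        new = current.copy()
        for j, preds in preds_of.items():
            obs_rows = [i for i in range(n) if not miss[i, j]]
            X = np.array([[1.0] + [current[i, p] for p in preds] for i in obs_rows])
            if len(obs_rows) < k + 1 or np.linalg.cond(X) > max_condition:
                for i in range(n):
                    if miss[i, j]:
                        new[i, j] = col_mean[j]
                continue
            y = np.array([values[i, j] for i in obs_rows])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            for i in range(n):
                if miss[i, j]:
                    new[i, j] = beta[0] + sum(
                        beta[t + 1] * current[i, p] for t, p in enumerate(preds)
                    )
        delta = np.mean((new - current) ** 2)
        current = new
        if iteration == 0:
            first_iterate = current.copy()
        if delta < tol:
            break
    else:
        current = first_iterate
    return current


def competition_ranks(scores: np.ndarray) -> np.ndarray:
    """Descending sort-based ranks; ties share the first (best) position."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    ranks = np.empty(len(scores), dtype=int)
    for pos, i in enumerate(order):
        if pos > 0 and scores[i] == scores[order[pos - 1]]:
            ranks[i] = ranks[order[pos - 1]]
        else:
            ranks[i] = pos + 1
    return ranks


def bartlett_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Textbook two-sample Bartlett chi-squared statistic and p-value."""
    groups = [np.asarray(x, float), np.asarray(y, float)]
    k = len(groups)
    n_i = np.array([len(g) for g in groups])
    s2_i = np.array([np.var(g, ddof=1) for g in groups])
    n = n_i.sum()
    sp2 = ((n_i - 1) * s2_i).sum() / (n - k)
    num = (n - k) * np.log(sp2) - ((n_i - 1) * np.log(s2_i)).sum()
    den = 1 + (np.sum(1 / (n_i - 1)) - 1 / (n - k)) / (3 * (k - 1))
    t = num / den
    return t, float(stats.chi2.sf(t, k - 1))
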