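"""Independent brute-force reference implementations used only by tests.

Deliberately naive: explicit loops, textbook formulas, normal-equation fits.
They share no code path with the package.
"""

import numpy as np
from scipy import stats


def brute_partial_corr(x, y, covariates=None):
    """Residualize-then-correlate with explicit OLS fits."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None:
        C = np.ones((n, 1))
        k = 0
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, float)])
        k = C.shape[1] - 1
    bx = np.linalg.solve(C.T @ C, C.T @ x)
    by = np.linalg.solve(C.T @ C, C.T @ y)
    rx = x - C @ bx
    ry = y - C @ by
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = n - 2 - k
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


def _ols_predict(X_tr, y_tr, x_te):
    X = np.column_stack([np.ones(len(y_tr)), X_tr])
    beta = np.linalg.solve(X.T @ X, X.T @ y_tr)
    return float(beta[0] + np.dot(np.atleast_1d(x_te), beta[1:]))


def brute_cpm_loocv(edges, y, covariates, threshold, zscore=True):
    """Naive LOOCV CPM: per-edge partial correlations, sign-split sums,
    per-model OLS fits, held-out prediction.  Returns observed, predictions
    and per-fold masks."""
    edges = np.asarray(edges, float)
    y = np.asarray(y, float)
    n, n_edges = edges.shape
    observed = np.empty(n)
    preds = {m: np.empty(n) for m in ("positive", "negative", "combined")}
    pos_masks = np.zeros((n, n_edges), bool)
    neg_masks = np.zeros((n, n_edges), bool)
    for i in range(n):
        tr = [j for j in range(n) if j != i]
        y_tr = y[tr]
        if zscore:
            mu, sd = y_tr.mean(), y_tr.std(ddof=1)
            y_tr = (y_tr - mu) / sd
            y_te = (y[i] - mu) / sd
        else:
            y_te = y[i]
        observed[i] = y_te
        cov_tr = None if covariates is None else np.asarray(covariates, float)[tr]
        for e in range(n_edges):
            r, p = brute_partial_corr(edges[tr, e], y_tr, cov_tr)
            if p < threshold:
                if r > 0:
                    pos_masks[i, e] = True
                elif r < 0:
                    neg_masks[i, e] = True
        s_pos = edges[:, pos_masks[i]].sum(axis=1)
        s_neg = edges[:, neg_masks[i]].sum(axis=1)
        has_pos, has_neg = pos_masks[i].any(), neg_masks[i].any()
        for m, cols in (
            ("positive", [s_pos] if has_pos else []),
            ("negative", [s_neg] if has_neg else []),
            # an all-zero summary column carries no information; dropping it
            # equals the minimum-norm OLS fit on the full design
            ("combined", [s for s, ok in ((s_pos, has_pos), (s_neg, has_neg)) if ok]),
        ):
            if not cols:
                preds[m][i] = y_tr.mean()
            else:
                X_tr = np.column_stack([c[tr] for c in cols])
                x_te = np.array([c[i] for c in cols])
                preds[m][i] = _ols_predict(X_tr, y_tr, x_te)
    acc = {
        m: float(np.corrcoef(observed, preds[m])[0, 1]) for m in preds
    }
    return observed, preds, acc, pos_masks, neg_masks


def spearman_oracle(a, b):
    """Rank-transform then Pearson, ranks by average-tie convention."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])
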