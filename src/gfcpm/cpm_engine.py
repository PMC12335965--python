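"""Connectome-based predictive modeling: LOOCV with covariate-controlled
univariate edge selection, positive/negative/combined summary models, and
permutation inference.

Per leave-one-out fold the engine (1) z-scores the behavior with training
mean/SD only (optional, on by default for the handwriting composite),
(2) retains edges whose partial correlation with behavior — controlling the
covariates — passes a two-sided p threshold, split by sign, (3) sums the
Fisher-z values over each retained set into positive/negative summary
features, (4) fits ordinary least squares on the training subjects and
predicts the held-out subject.  Prediction accuracy is the Pearson
correlation between observed and predicted scores across folds; its
significance comes from rerunning the whole procedure on behavior-permuted
data, with p = (1 + #{permuted accuracy >= true}) / (1 + n_permutations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MODELS = ("positive", "negative", "combined")

#: residual-norm floor (relative to the raw column norm) below which an edge
#: is treated as degenerate and excluded from selection
_DEGENERATE_RTOL = 1e-10


class DegenerateBehaviorError(ValueError):
    pass


@dataclass
class CPMConfig:
    """Knobs of the CPM procedure.

    threshold
        Two-sided p threshold of the edge-selection partial correlation
        (default 0.001; 0.0025 and 0.0005 are the validation alternates).
    zscore_behavior
        Train-fold z-scoring of the behavior (on for the handwriting
        composite, off for raw reading scores).
    """

    threshold: float = 0.001
    models: tuple[str, ...] = MODELS
    n_permutations: int = 1000
    seed: int = 0
    zscore_behavior: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        unknown = set(self.models) - set(MODELS)
        if unknown:
            raise ValueError(f"unknown model(s): {sorted(unknown)}")


@dataclass
class CPMResult:
    """LOOCV output: per-fold masks, per-model predictions and accuracies."""

    observed: np.ndarray                    #: behavior on the per-fold scale
    predictions: dict[str, np.ndarray]
    accuracy: dict[str, float]
    pos_masks: np.ndarray                   #: folds x edges, bool
    neg_masks: np.ndarray
    coefficients: dict[str, np.ndarray]     #: folds x (intercept + slopes)
    n_empty_folds: dict[str, int]
    p_permutation: dict[str, float] | None = None

    @property
    def n_folds(self) -> int:
        return self.pos_masks.shape[0]


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _residualize(v: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residual of ``v`` against the orthonormal columns ``Q``."""
    return v - Q @ (Q.T @ v)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both vectors are residualized on [intercept | covariates] and the
    residuals correlated; the two-sided p uses a t distribution with
    df = n - 2 - k.  With no covariates this reduces to the plain Pearson
    correlation and its textbook p.  Returns (nan, nan) when either residual
    has (numerically) zero variance so the caller can skip the edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariates must have one row per subject")
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), C]))
    rx = _residualize(x, Q)
    ry = _residualize(y, Q)
    nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
    if nx <= _DEGENERATE_RTOL * max(1.0, np.linalg.norm(x)) or \
       ny <= _DEGENERATE_RTOL * max(1.0, np.linalg.norm(y)):
        return float("nan"), float("nan")
    r = float(np.clip(rx @ ry / (nx * ny), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def zscore_train_apply(
    train: np.ndarray, test: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score with training mean and sample SD only (no test leakage)."""
    train = np.asarray(train, dtype=float)
    if len(train) < 2:
        raise ValueError("need at least 2 training values")
    mu = train.mean()
    sd = train.std(ddof=1)
    if sd == 0:
        raise DegenerateBehaviorError("zero training SD")
    return (train - mu) / sd, (np.asarray(test, dtype=float) - mu) / sd


def r_critical(threshold: float, df: int) -> float:
    """|partial r| above which the two-sided p falls below ``threshold``."""
    t = stats.t.isf(threshold / 2.0, df)
    return float(t / np.hypot(t, np.sqrt(df)))


def select_features(
    edges: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None,
    threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sign-split edge selection on training data.

    Returns boolean masks over edges: partial r > 0 with p < threshold, and
    partial r < 0 with p < threshold.  Degenerate (zero residual variance)
    edges are never selected; their count is logged.
    """
    edges = np.asarray(edges, dtype=float)
    n, _ = edges.shape
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), C]))
    ry = _residualize(np.asarray(behavior, float), Q)
    ny = np.linalg.norm(ry)
    if ny == 0:
        raise DegenerateBehaviorError("behavior has zero residual variance")
    R = edges - Q @ (Q.T @ edges)
    norms = np.linalg.norm(R, axis=0)
    valid = norms > _DEGENERATE_RTOL * np.maximum(1.0, np.linalg.norm(edges, axis=0))
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("skipping %d degenerate edge(s)", n_bad)
    r = np.zeros(edges.shape[1])
    r[valid] = (R[:, valid].T @ ry) / (norms[valid] * ny)
    rc = r_critical(threshold, n - 2 - C.shape[1])
    sig = np.abs(r) > rc
    return (sig & (r > 0) & valid), (sig & (r < 0) & valid)


def summary_features(
    edge_vector: np.ndarray, pos_mask: np.ndarray, neg_mask: np.ndarray
) -> tuple[float, float]:
    """Plain sums of Fisher-z values over the positive and negative sets."""
    v = np.asarray(edge_vector, dtype=float)
    return float(v[pos_mask].sum()), float(v[neg_mask].sum())


def prediction_accuracy(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between observed and predicted scores."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or len(o) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if o.std() == 0 or p.std() == 0:
        raise DegenerateBehaviorError("zero variance; accuracy undefined")
    return float(np.corrcoef(o, p)[0, 1])


# ---------------------------------------------------------------------------
# LOOCV engine
# ---------------------------------------------------------------------------

class _FoldCache:
    """Per-fold quantities that do not depend on the behavior vector.

    Because permutations shuffle behavior only (covariates stay attached to
    their subjects), the covariate-residualized, unit-normalized training
    edge matrices can be computed once and reused across all permutations.
    """

    def __init__(self, edges: np.ndarray, covariates: np.ndarray | None):
        edges = np.asarray(edges, dtype=float)
        n, n_edges = edges.shape
        C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
        if C.size and C.shape[0] != n:
            raise ValueError("covariates must have one row per subject")
        self.edges = edges
        self.n, self.n_edges = n, n_edges
        self.df = n - 1 - 2 - C.shape[1]
        if self.df < 1:
            raise ValueError("too few subjects for the number of covariates")
        col_norm = np.maximum(1.0, np.linalg.norm(edges, axis=0))
        self.train_idx: list[np.ndarray] = []
        self.Q: list[np.ndarray] = []
        self.R_unit: list[np.ndarray] = []
        self.valid: list[np.ndarray] = []
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            Q, _ = np.linalg.qr(np.column_stack([np.ones(n - 1), C[tr]]))
            R = edges[tr] - Q @ (Q.T @ edges[tr])
            norms = np.linalg.norm(R, axis=0)
            valid = norms > _DEGENERATE_RTOL * col_norm
            Ru = np.zeros_like(R)
            Ru[:, valid] = R[:, valid] / norms[valid]
            self.train_idx.append(tr)
            self.Q.append(Q)
            self.R_unit.append(Ru)
            self.valid.append(valid)


def _fit_predict(s_tr: np.ndarray, y_tr: np.ndarray, s_te: np.ndarray) -> tuple[float, np.ndarray]:
    """OLS of y on [1 | s]; returns the test prediction and coefficients."""
    X = np.column_stack([np.ones(len(y_tr)), s_tr])
    beta, *_ = np.linalg.lstsq(X, y_tr, rcond=None)
    return float(beta[0] + s_te @ beta[1:]), beta


def _loocv_core(
    cache: _FoldCache, behavior: np.ndarray, config: CPMConfig, collect: bool
):
    """One full LOOCV pass over a (possibly permuted) behavior vector."""
    n, models = cache.n, config.models
    rc = r_critical(config.threshold, cache.df)
    observed = np.empty(n)
    preds = {m: np.empty(n) for m in models}
    pos_masks = np.zeros((n, cache.n_edges), dtype=bool) if collect else None
    neg_masks = np.zeros((n, cache.n_edges), dtype=bool) if collect else None
    coefs: dict[str, list[np.ndarray]] = {m: [] for m in models} if collect else {}
    n_empty = dict.fromkeys(models, 0)
    for i in range(n):
        tr = cache.train_idx[i]
        if config.zscore_behavior:
            y_tr, y_te = zscore_train_apply(behavior[tr], behavior[i])
        else:
            y_tr, y_te = behavior[tr], float(behavior[i])
        observed[i] = y_te
        ry = _residualize(y_tr, cache.Q[i])
        ny = np.linalg.norm(ry)
        if ny == 0:
            raise DegenerateBehaviorError("behavior constant within a training fold")
        r = ry @ cache.R_unit[i] / ny
        sig = np.abs(r) > rc
        pos = sig & (r > 0)
        neg = sig & (r < 0)
        E_tr, E_te = cache.edges[tr], cache.edges[i]
        s_pos_tr, s_neg_tr = E_tr[:, pos].sum(axis=1), E_tr[:, neg].sum(axis=1)
        s_pos_te, s_neg_te = E_te[pos].sum(), E_te[neg].sum()
        feats = {
            "positive": (s_pos_tr[:, None], np.array([s_pos_te]), pos.any()),
            "negative": (s_neg_tr[:, None], np.array([s_neg_te]), neg.any()),
            "combined": (
                np.column_stack([s_pos_tr, s_neg_tr]),
                np.array([s_pos_te, s_neg_te]),
                pos.any() or neg.any(),
            ),
        }
        for m in models:
            s_tr, s_te, any_sel = feats[m]
            if not any_sel:
                n_empty[m] += 1
                pred, beta = float(y_tr.mean()), np.array([y_tr.mean()])
            else:
                pred, beta = _fit_predict(s_tr, y_tr, s_te)
            preds[m][i] = pred
            if collect:
                coefs[m].append(beta)
        if collect:
            pos_masks[i] = pos
            neg_masks[i] = neg
    acc = {}
    for m in models:
        try:
            acc[m] = prediction_accuracy(observed, preds[m])
        except DegenerateBehaviorError:
            acc[m] = float("nan")
    return observed, preds, acc, pos_masks, neg_masks, coefs, n_empty


def loocv_predict(
    edges: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None,
    config: CPMConfig | None = None,
) -> CPMResult:
    """Leave-one-out CPM on a subjects-x-edges matrix.

    Per fold, feature selection and behavior normalization see the training
    subjects only; folds that select no edge for a model fall back to an
    intercept-only prediction (counted in ``n_empty_folds``).
    """
    config = config or CPMConfig()
    edges = np.asarray(edges, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if edges.shape[0] != len(behavior):
        raise ValueError("edges and behavior disagree on subject count")
    if edges.shape[0] < 10:
        raise ValueError("need at least 10 subjects for LOOCV")
    if not (np.all(np.isfinite(edges)) and np.all(np.isfinite(behavior))):
        raise ValueError("missing/non-finite values are not supported")
    cache = _FoldCache(edges, covariates)
    observed, preds, acc, pos, neg, coefs, n_empty = _loocv_core(
        cache, behavior, config, collect=True
    )
    for m, k in n_empty.items():
        if k:
            logger.info("%s model: %d fold(s) with empty selection", m, k)
    return CPMResult(
        observed=observed,
        predictions=preds,
        accuracy=acc,
        pos_masks=pos,
        neg_masks=neg,
        coefficients={m: np.array(v, dtype=object) for m, v in coefs.items()},
        n_empty_folds=n_empty,
    )


def permutation_test(
    edges: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None,
    config: CPMConfig | None = None,
    true_accuracy: dict[str, float] | None = None,
) -> dict[str, float]:
    """Permutation p per model: behavior is shuffled across subjects (the
    covariates stay with their subjects) and the full LOOCV is rerun each
    time; p = (1 + #{permuted accuracy >= true}) / (1 + n_permutations).

    With all permutations beaten at N = 1000 the floor is 1/1001 ~ 0.001.
    """
    config = config or CPMConfig()
    edges = np.asarray(edges, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    cache = _FoldCache(edges, covariates)
    if true_accuracy is None:
        _, _, true_accuracy, *_ = _loocv_core(cache, behavior, config, collect=False)
    rng = np.random.default_rng(config.seed)
    exceed = dict.fromkeys(config.models, 0)
    for _ in range(config.n_permutations):
        y = rng.permutation(behavior)
        try:
            _, _, acc, *_ = _loocv_core(cache, y, config, collect=False)
        except DegenerateBehaviorError:
            continue
        for m in config.models:
            if np.isfinite(acc[m]) and acc[m] >= true_accuracy[m]:
                exceed[m] += 1
    return {
        m: (1 + exceed[m]) / (1 + config.n_permutations) for m in config.models
    }
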