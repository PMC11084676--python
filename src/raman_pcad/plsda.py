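"""PLS-DA: NIPALS PLS1 fitting, thresholded classification,
random-subset cross-validation, latent-variable selection, metrics and
permutation testing.

The class response is coded H -> 0, PC -> 1 and the model is an
ordinary single-response PLS regression on the mean-centered spectra
(no autoscaling: spectra are already SNV-scaled); classification
applies a decision threshold (default 0.5) to the predicted response.
Cross-validation follows the random-subset scheme: the patients are
partitioned at random into ``n_subsets`` stratified folds and every
fold is predicted from a model fitted on its complement; the whole
partition is redrawn ``n_iterations`` times and errors are pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PLSDAModel",
    "CVConfig",
    "CVResult",
    "Metrics",
    "PermutationResult",
    "fit_pls",
    "predict",
    "classify",
    "compute_metrics",
    "cross_validate",
    "select_n_lvs",
    "permutation_test",
    "bayes_threshold",
]

CLASS_CODING = {"H": 0.0, "PC": 1.0}


@dataclass
class PLSDAModel:
    """A fitted PLS1 discriminant model.

    ``w`` holds the (unit-norm) NIPALS weight vectors, ``p_load`` the
    X-loadings, ``q`` the y-loadings and ``t_scores`` the training
    scores, one column per latent variable.  ``b`` is the collapsed
    regression vector: predictions are
    ``(X - x_mean) @ b + y_mean``.
    """

    x_mean: np.ndarray
    y_mean: float
    w: np.ndarray
    p_load: np.ndarray
    q: np.ndarray
    t_scores: np.ndarray
    b: np.ndarray
    n_lv: int
    threshold: float = 0.5
    class_coding: dict = field(default_factory=lambda: dict(CLASS_CODING))
    selected_variables: np.ndarray | None = None


@dataclass(frozen=True)
class CVConfig:
    """Random-subset cross-validation settings (default 15 subsets,
    5 iterations)."""

    n_subsets: int = 15
    n_iterations: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_subsets < 2:
            raise ValueError("n_subsets must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Metrics:
    """Standard binary classification figures of merit; positive class
    is PC."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: dict[str, int]


@dataclass
class CVResult:
    """Cross-validated predictions and pooled figures of merit.

    ``yhat_cv`` has shape (n_iterations, n_samples): every sample is
    predicted exactly once per iteration.  ``rmsecv`` pools the squared
    errors over samples and iterations.
    """

    yhat_cv: np.ndarray
    rmsecv: float
    metrics: Metrics
    per_iteration_metrics: list[Metrics]
    n_lv: int


@dataclass
class PermutationResult:
    observed_metric: float
    null_metrics: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    metric: str


def _encode_y(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        return np.array([CLASS_CODING[str(v)] for v in y], dtype=float)
    return y.astype(float)


def _nipals_pls1(
    xc: np.ndarray, yc: np.ndarray, n_lv: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS deflation on centered data.  For a single response each
    weight vector is closed-form (``w = X'y / |X'y|``), so the fit is
    deterministic.  Stops early (returning fewer components) if the
    residual covariance vanishes, i.e. the data rank is exhausted."""
    n, p = xc.shape
    xc = xc.copy()
    yc = yc.copy()
    ws, ps, qs, ts = [], [], [], []
    for _ in range(n_lv):
        wa = xc.T @ yc
        norm = np.linalg.norm(wa)
        if norm < 1e-12:
            break
        wa /= norm
        t = xc @ wa
        tt = t @ t
        if tt < 1e-12:
            break
        pa = xc.T @ t / tt
        qa = (yc @ t) / tt
        xc -= np.outer(t, pa)
        yc = yc - qa * t
        ws.append(wa)
        ps.append(pa)
        qs.append(qa)
        ts.append(t)
    if not ws:
        raise ValueError("no PLS component could be extracted (X'y = 0)")
    return (
        np.column_stack(ws),
        np.column_stack(ps),
        np.array(qs),
        np.column_stack(ts),
    )


def fit_pls(x: np.ndarray, y: np.ndarray, n_lv: int) -> PLSDAModel:
    """Fit single-response PLS by NIPALS with X-deflation."""
    x = np.asarray(x, dtype=float)
    y = _encode_y(y)
    n, p = x.shape
    if y.shape != (n,):
        raise ValueError("y must have one entry per row of x")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance: both classes must be present")
    max_lv = min(n - 1, p)
    if not 1 <= n_lv <= max_lv:
        raise ValueError(f"n_lv must be in [1, {max_lv}], got {n_lv}")

    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    w, p_load, q, t_scores = _nipals_pls1(x - x_mean, y - y_mean, n_lv)
    if w.shape[1] < n_lv:
        raise ValueError(
            f"data rank supports only {w.shape[1]} components, "
            f"requested {n_lv}"
        )
    # collapse the factor model to one regression vector
    b = w @ np.linalg.solve(p_load.T @ w, q)
    return PLSDAModel(
        x_mean=x_mean,
        y_mean=y_mean,
        w=w,
        p_load=p_load,
        q=q,
        t_scores=t_scores,
        b=b,
        n_lv=n_lv,
    )


def predict(model: PLSDAModel, x_new: np.ndarray) -> np.ndarray:
    """Continuous predicted response for new spectra."""
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    if x_new.shape[1] != model.x_mean.size:
        expected = model.x_mean.size
        raise ValueError(
            f"variable mismatch: model expects {expected} wavenumbers, "
            f"got {x_new.shape[1]}"
        )
    return (x_new - model.x_mean) @ model.b + model.y_mean


def transform(model: PLSDAModel, x_new: np.ndarray) -> np.ndarray:
    """Project spectra onto the model's latent variables (scores)."""
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    xc = x_new - model.x_mean
    t = np.zeros((x_new.shape[0], model.n_lv))
    for a in range(model.n_lv):
        t[:, a] = xc @ model.w[:, a]
        xc = xc - np.outer(t[:, a], model.p_load[:, a])
    return t


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold continuous predictions into class labels; a prediction
    exactly at the threshold is assigned to H."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > threshold, "PC", "H")


def _auc_rank(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank statistic with midrank tie
    correction."""
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def compute_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> Metrics:
    """Confusion-matrix metrics at the given threshold plus
    rank-statistic AUC.  Positive class is PC (coded 1)."""
    y = _encode_y(y_true)
    scores = np.asarray(scores, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("both classes must be present to compute metrics")
    pred = (scores > threshold).astype(float)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return Metrics(
        auc=_auc_rank(y, scores),
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        confusion={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
    )


def _stratified_folds(
    y: np.ndarray, n_subsets: int, rng: np.random.Generator, stratified: bool
) -> np.ndarray:
    """Assign each sample to one of ``n_subsets`` folds; with
    stratification, each class is dealt round-robin so folds are
    class-balanced to within one sample."""
    n = y.size
    fold = np.empty(n, dtype=int)
    if stratified:
        start = 0
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            fold[idx] = (start + np.arange(idx.size)) % n_subsets
            start += idx.size
    else:
        idx = rng.permutation(n)
        fold[idx] = np.arange(n) % n_subsets
    return fold


_REDRAW_CAP = 100


def _cv_predictions(
    x: np.ndarray, y: np.ndarray, max_lv: int, cv: CVConfig
) -> np.ndarray:
    """Cross-validated predictions for every LV count 1..max_lv.

    Returns an array of shape (n_iterations, n, max_lv).  Each
    iteration draws a fresh random (stratified) partition into
    ``cv.n_subsets`` folds; a partition whose training complement
    misses a class is redrawn (up to a cap).  One NIPALS pass per
    training split yields the predictions at every truncation depth.
    """
    x = np.asarray(x, dtype=float)
    y = _encode_y(y)
    n = x.shape[0]
    if n < cv.n_subsets:
        raise ValueError(
            f"need at least n_subsets={cv.n_subsets} samples, got {n}"
        )
    rng = np.random.default_rng(cv.seed)
    yhat = np.empty((cv.n_iterations, n, max_lv))
    for it in range(cv.n_iterations):
        for attempt in range(_REDRAW_CAP):
            fold = _stratified_folds(y, cv.n_subsets, rng, cv.stratified)
            ok = all(
                np.ptp(y[fold != k]) > 0 for k in range(cv.n_subsets)
            )
            if ok:
                break
            warnings.warn(
                "cross-validation partition left a training split with a "
                "single class; redrawing",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            raise RuntimeError("could not draw a valid CV partition")
        for k in range(cv.n_subsets):
            test = fold == k
            if not test.any():
                continue
            xtr, ytr = x[~test], y[~test]
            a_cap = min(max_lv, xtr.shape[0] - 1, xtr.shape[1])
            x_mean = xtr.mean(axis=0)
            y_mean = ytr.mean()
            w, p_load, q, _ = _nipals_pls1(xtr - x_mean, ytr - y_mean, a_cap)
            a_got = w.shape[1]
            # accumulate predictions truncation-by-truncation; beyond the
            # training split's rank the prediction stays at its last value
            xc = x[test] - x_mean
            acc = np.full(int(test.sum()), y_mean)
            for a in range(max_lv):
                if a < a_got:
                    t = xc @ w[:, a]
                    acc = acc + q[a] * t
                    xc = xc - np.outer(t, p_load[:, a])
                yhat[it, test, a] = acc
    return yhat


def cross_validate(
    x: np.ndarray, y: np.ndarray, n_lv: int, cv: CVConfig
) -> CVResult:
    """Random-subset cross-validation at a fixed LV count.

    RMSECV pools the squared prediction errors over all samples and
    iterations; the headline metrics are computed from the pooled
    cross-validated predictions (all iterations concatenated), with
    per-iteration metrics reported alongside.
    """
    yc = _encode_y(y)
    yhat = _cv_predictions(x, y, n_lv, cv)[:, :, n_lv - 1]
    rmsecv = float(np.sqrt(np.mean((yhat - yc[None, :]) ** 2)))
    pooled_scores = yhat.reshape(-1)
    pooled_y = np.tile(yc, cv.n_iterations)
    metrics = compute_metrics(pooled_y, pooled_scores)
    per_iter = [compute_metrics(yc, yhat[i]) for i in range(cv.n_iterations)]
    return CVResult(
        yhat_cv=yhat,
        rmsecv=rmsecv,
        metrics=metrics,
        per_iteration_metrics=per_iter,
        n_lv=n_lv,
    )


def select_n_lvs(
    x: np.ndarray, y: np.ndarray, max_lv: int, cv: CVConfig
) -> tuple[int, np.ndarray]:
    """Tune the number of latent variables by minimizing RMSECV over
    1..max_lv; ties break toward fewer LVs.  Returns the chosen count
    and the full RMSECV curve."""
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    x = np.asarray(x, dtype=float)
    yc = _encode_y(y)
    hard_cap = min(max_lv, x.shape[0] - 1, x.shape[1])
    yhat = _cv_predictions(x, y, hard_cap, cv)
    err = yhat - yc[None, :, None]
    curve = np.sqrt(np.mean(err**2, axis=(0, 1)))
    best = int(np.argmin(curve)) + 1  # argmin takes the first (fewest-LV) minimum
    return best, curve


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    cv: CVConfig,
    n_perm: int = 99,
    metric: str = "accuracy",
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation test of a cross-validated PLS-DA model.

    The observed metric comes from a full cross-validation on the true
    labels; each permutation reshuffles the labels and reruns the
    entire cross-validation.  The p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if metric not in ("accuracy", "auc"):
        raise ValueError("metric must be 'accuracy' or 'auc'")
    yc = _encode_y(y)
    observed = getattr(cross_validate(x, yc, n_lv, cv).metrics, metric)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(yc)
        cv_i = replace(cv, seed=int(rng.integers(0, 2**31)))
        null[i] = getattr(cross_validate(x, yp, n_lv, cv_i).metrics, metric)
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PermutationResult(
        observed_metric=float(observed),
        null_metrics=null,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        metric=metric,
    )


def bayes_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Decision threshold at the intersection of class-conditional
    Gaussians fitted to (cross-validated) predicted responses — the
    usual alternative to the fixed midpoint cut in chemometrics
    toolboxes.  Falls back to the midpoint of class means when the
    quadratic has no root between them."""
    yc = _encode_y(y)
    s0, s1 = scores[yc == 0], scores[yc == 1]
    m0, m1 = s0.mean(), s1.mean()
    v0, v1 = s0.var(ddof=1), s1.var(ddof=1)
    if v0 <= 0 or v1 <= 0:
        return float((m0 + m1) / 2)
    a = 1 / v0 - 1 / v1
    b = -2 * (m0 / v0 - m1 / v1)
    c = m0**2 / v0 - m1**2 / v1 + np.log(v0 / v1)
    if abs(a) < 1e-12:
        return float(-c / b) if b != 0 else float((m0 + m1) / 2)
    disc = b**2 - 4 * a * c
    if disc < 0:
        return float((m0 + m1) / 2)
    roots = (-b + np.array([1.0, -1.0]) * np.sqrt(disc)) / (2 * a)
    lo, hi = min(m0, m1), max(m0, m1)
    inside = roots[(roots >= lo) & (roots <= hi)]
    return float(inside[0]) if inside.size else float((m0 + m1) / 2)
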