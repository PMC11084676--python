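"""Variable selection for PLS-DA spectral models.

Implements the two classical per-variable importance measures — VIP
(variable importance in projection, Chong-Jun form) and the
selectivity ratio (target-projection form, Rajalahti) — and combines
them in an RMSECV-driven backward elimination: at each step the
variables with the worst combined VIP/SR rank are removed, the model
is re-tuned and re-cross-validated, and elimination stops once the
error no longer improves.  Stability of the selection is assessed by a
jackknife: the elimination is rerun many times, each time excluding a
few patients per class at random, and every wavenumber's selection
frequency is counted.  Thresholding these frequencies yields a family
of reduced models whose figures of merit can be scanned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .plsda import (
    CVConfig,
    PLSDAModel,
    _encode_y,
    cross_validate,
    fit_pls,
    select_n_lvs,
)

__all__ = [
    "VariableScores",
    "SelectionResult",
    "FrequencyTable",
    "vip_scores",
    "selectivity_ratio",
    "combined_rank",
    "iterative_selection",
    "stability_selection",
    "threshold_scan",
]

SR_CAP = 1e12


@dataclass
class VariableScores:
    """Per-variable VIP and selectivity-ratio scores of one fitted
    model.  VIP is normalized so that mean(VIP^2) = 1."""

    vip: np.ndarray
    sr: np.ndarray
    variable_ids: np.ndarray


@dataclass
class SelectionResult:
    """Outcome of one backward-elimination run.

    ``selected`` holds column indices into the matrix the elimination
    started from; the returned subset is the one with the minimum
    RMSECV seen anywhere along the trajectory.
    """

    selected: np.ndarray
    rmsecv_trajectory: np.ndarray
    n_lv_per_step: np.ndarray
    stop_reason: str  # "no_improvement" | "floor_reached"
    subsets: list[np.ndarray]

    @property
    def best_rmsecv(self) -> float:
        return float(np.min(self.rmsecv_trajectory))


@dataclass
class FrequencyTable:
    """Selection counts per wavenumber over jackknife iterations."""

    variable_ids: np.ndarray
    counts: np.ndarray
    n_iterations: int

    def __post_init__(self) -> None:
        self.variable_ids = np.asarray(self.variable_ids)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.min() < 0 or self.counts.max() > self.n_iterations:
            raise ValueError("counts must lie in [0, n_iterations]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavenumber": self.variable_ids, "count": self.counts}
        )


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / |w_a|)^2 / sum_a SSY_a ),
    where SSY_a = q_a^2 t_a't_a is the y-variance explained by
    component a.  The normalization makes mean(VIP^2) = 1, so VIP > 1
    marks variables contributing more than average.
    """
    w = model.w
    p = w.shape[0]
    norms = np.linalg.norm(w, axis=0)
    if np.any(norms < 1e-300):
        raise ValueError("degenerate component with zero weight norm")
    ssy = model.q**2 * np.einsum("ia,ia->a", model.t_scores, model.t_scores)
    wn2 = (w / norms) ** 2
    return np.sqrt(p * (wn2 @ ssy) / ssy.sum())


def selectivity_ratio(model: PLSDAModel, x: np.ndarray) -> np.ndarray:
    """Selectivity ratio via target projection.

    The training matrix is projected onto the normalized regression
    vector v = b/|b| (the target-projection direction); for each
    variable the ratio of explained to residual sum of squares is
    returned.  A variable fully explained by the projection has zero
    residual; its ratio is capped at a large sentinel.
    """
    x = np.asarray(x, dtype=float)
    xc = x - model.x_mean
    v = model.b / np.linalg.norm(model.b)
    t_tp = xc @ v
    x_tp = np.outer(t_tp, v)
    explained = np.sum(x_tp**2, axis=0)
    residual = np.sum((xc - x_tp) ** 2, axis=0)
    sr = np.empty_like(explained)
    zero = residual <= explained * 1e-15
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} variable(s) with zero residual variance; "
            "selectivity ratio capped",
            RuntimeWarning,
            stacklevel=2,
        )
    sr[zero] = SR_CAP
    np.divide(explained, residual, out=sr, where=~zero)
    return sr


def combined_rank(vip: np.ndarray, sr: np.ndarray) -> np.ndarray:
    """Scale-free combined influence: the sum of the ascending ranks of
    VIP and SR.  Low combined rank = low influence on prediction."""
    return rankdata(vip) + rankdata(sr)


def iterative_selection(
    x: np.ndarray,
    y: np.ndarray,
    cv: CVConfig,
    drop_fraction: float = 0.1,
    min_variables: int = 10,
    max_lv: int = 10,
    rel_tol: float = 0.01,
) -> SelectionResult:
    """Backward elimination of wavenumbers driven by cross-validated
    error.

    Each step (i) tunes the LV count on the current subset, (ii) fits
    the model and scores every variable by VIP and SR, (iii) drops the
    ``drop_fraction`` of variables with the worst combined rank (at
    least one), and (iv) records the subset's RMSECV.  Elimination
    stops when the error exceeds the best seen by more than ``rel_tol``
    (relative) or when ``min_variables`` is reached; the subset with
    the minimum RMSECV over the whole trajectory is returned.
    """
    x = np.asarray(x, dtype=float)
    y = _encode_y(y)
    p = x.shape[1]
    if min_variables < 1:
        raise ValueError("min_variables must be >= 1")
    if min_variables > p:
        raise ValueError(f"min_variables={min_variables} exceeds p={p}")
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must lie in (0, 1)")

    current = np.arange(p)
    trajectory: list[float] = []
    n_lvs: list[int] = []
    subsets: list[np.ndarray] = []
    best = np.inf
    stop_reason = "floor_reached"
    while True:
        xs = x[:, current]
        n_lv, curve = select_n_lvs(xs, y, max_lv, cv)
        rmsecv = float(curve[n_lv - 1])
        trajectory.append(rmsecv)
        n_lvs.append(n_lv)
        subsets.append(current.copy())
        if rmsecv > best * (1.0 + rel_tol):
            stop_reason = "no_improvement"
            break
        best = min(best, rmsecv)
        if current.size <= min_variables:
            stop_reason = "floor_reached"
            break
        model = fit_pls(xs, y, n_lv)
        rank = combined_rank(vip_scores(model), selectivity_ratio(model, xs))
        n_drop = max(1, int(drop_fraction * current.size))
        n_drop = min(n_drop, current.size - min_variables)
        order = np.argsort(rank, kind="stable")
        current = np.delete(current, order[:n_drop])

    i_best = int(np.argmin(trajectory))
    selected = subsets[i_best]
    return SelectionResult(
        selected=selected,
        rmsecv_trajectory=np.array(trajectory),
        n_lv_per_step=np.array(n_lvs),
        stop_reason=stop_reason,
        subsets=subsets,
    )


def stability_selection(
    x: np.ndarray,
    y: np.ndarray,
    cv: CVConfig,
    n_iter: int = 100,
    holdout_per_class: int = 5,
    seed: int = 0,
    variable_ids: np.ndarray | None = None,
    **selection_kwargs,
) -> FrequencyTable:
    """Jackknife stability selection.

    Runs the backward elimination ``n_iter`` times; each run excludes
    ``holdout_per_class`` patients per class uniformly at random and
    keeps the same cross-validation structure, so both interclass and
    intraclass variability perturb the selection.  Counts how often
    each wavenumber survives.  Per-iteration randomness is derived from
    one master seed, so the whole procedure is reproducible.
    """
    x = np.asarray(x, dtype=float)
    yc = _encode_y(y)
    n = x.shape[0]
    for c in (0.0, 1.0):
        if np.sum(yc == c) <= holdout_per_class:
            raise ValueError(
                "holdout_per_class must be smaller than each class size"
            )
    if variable_ids is None:
        variable_ids = np.arange(x.shape[1])
    counts = np.zeros(x.shape[1], dtype=int)
    children = np.random.SeedSequence(seed).spawn(n_iter)
    for it in range(n_iter):
        rng = np.random.default_rng(children[it])
        keep = np.ones(n, dtype=bool)
        for c in (0.0, 1.0):
            idx = np.flatnonzero(yc == c)
            keep[rng.choice(idx, size=holdout_per_class, replace=False)] = False
        cv_it = replace(cv, seed=int(rng.integers(0, 2**31)))
        res = iterative_selection(x[keep], yc[keep], cv_it, **selection_kwargs)
        counts[res.selected] += 1
    return FrequencyTable(
        variable_ids=np.asarray(variable_ids), counts=counts, n_iterations=n_iter
    )


def threshold_scan(
    x: np.ndarray,
    y: np.ndarray,
    freq: FrequencyTable,
    thresholds: np.ndarray,
    cv: CVConfig,
    max_lv: int = 10,
) -> tuple[pd.DataFrame, int]:
    """Figures of merit of frequency-thresholded models.

    For each threshold f the model keeps the wavenumbers selected
    strictly more than f times, re-tunes the LV count and
    cross-validates.  Returns the metric table and the
    accuracy-maximizing threshold (ties resolved toward the larger
    threshold, i.e. the sparser model).  A threshold that empties the
    variable set yields a flagged NaN row.
    """
    thresholds = np.asarray(thresholds, dtype=int)
    if thresholds.min() < 0 or thresholds.max() > freq.n_iterations:
        raise ValueError("thresholds must lie within [0, n_iterations]")
    rows = []
    for f in thresholds:
        keep = np.flatnonzero(freq.counts > f)
        if keep.size == 0:
            rows.append(
                {
                    "threshold": int(f),
                    "n_variables": 0,
                    "n_lv": 0,
                    "rmsecv": np.nan,
                    "auc": np.nan,
                    "accuracy": np.nan,
                    "sensitivity": np.nan,
                    "specificity": np.nan,
                    "empty": True,
                }
            )
            continue
        xs = np.asarray(x, dtype=float)[:, keep]
        n_lv, curve = select_n_lvs(xs, y, max_lv, cv)
        res = cross_validate(xs, y, n_lv, cv)
        rows.append(
            {
                "threshold": int(f),
                "n_variables": int(keep.size),
                "n_lv": n_lv,
                "rmsecv": res.rmsecv,
                "auc": res.metrics.auc,
                "accuracy": res.metrics.accuracy,
                "sensitivity": res.metrics.sensitivity,
                "specificity": res.metrics.specificity,
                "empty": False,
            }
        )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["accuracy"])
    if valid.empty:
        raise ValueError("every threshold left an empty variable set")
    best_acc = valid["accuracy"].max()
    best = int(valid.loc[valid["accuracy"] == best_acc, "threshold"].max())
    return table, best
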