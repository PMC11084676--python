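"""End-to-end experiment orchestration.

Reproduces the study's model-building matrix on a (synthetic or
loaded) two-cohort patient table:

1. a per-cohort model for each dataset (variable selection, LV tuning,
   random-subset cross-validation);
2. a combined model on the pooled cohorts;
3. a "common-variables" model restricted to the wavenumbers selected
   in *all three* of the above selections;
4. a frequency-threshold model: jackknife stability selection followed
   by a scan over selection-frequency thresholds, keeping the
   accuracy-optimal threshold;
5. a label-permutation test of the headline (threshold) model.

Every run is driven by one master seed and writes a manifest
sufficient to replay it bit-identically.  Variable selection runs
before (outside) the final model's cross-validation, mirroring the
usual chemometrics practice; an optional nested evaluation
(`nested_cv_metrics`) re-runs the selection inside every outer fold
for a bias-free estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .plsda import (
    CVConfig,
    PLSDAModel,
    compute_metrics,
    cross_validate,
    fit_pls,
    permutation_test,
    select_n_lvs,
    transform,
)
from .preprocess import (
    PatientTable,
    PreprocessConfig,
    average_per_patient,
    preprocess_dataset,
)
from .synthgen import SpectralDataset, SynthConfig, generate_study
from .varsel import (
    FrequencyTable,
    SelectionResult,
    iterative_selection,
    stability_selection,
    threshold_scan,
)

__all__ = [
    "RunConfig",
    "ModelRun",
    "ExperimentReport",
    "run_cohort_model",
    "run_combined_model",
    "export_scores",
    "run_full_pipeline",
    "nested_cv_metrics",
]

STAGE_ORDER = (
    "simulate_or_load",
    "preprocess",
    "average_per_patient",
    "variable_selection",
    "model_training",
    "validation",
)

REPORT_COLUMNS = [
    "cohort",
    "matrix",
    "auc",
    "accuracy",
    "sensitivity",
    "specificity",
    "n_lv",
    "n_variables",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to replay a full experiment."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    drop_fraction: float = 0.1
    min_variables: int = 10
    max_lv: int = 10
    stability_n_iter: int = 100
    holdout_per_class: int = 5
    thresholds: tuple[int, ...] = (0, 10, 20, 30, 40, 50, 60, 70, 80, 90)
    n_permutations: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.thresholds, tuple):
            object.__setattr__(self, "thresholds", tuple(self.thresholds))

    def to_dict(self) -> dict:
        return {
            "synth": self.synth.to_dict(),
            "preprocess": self.preprocess.to_dict(),
            "cv": self.cv.to_dict(),
            "drop_fraction": self.drop_fraction,
            "min_variables": self.min_variables,
            "max_lv": self.max_lv,
            "stability_n_iter": self.stability_n_iter,
            "holdout_per_class": self.holdout_per_class,
            "thresholds": list(self.thresholds),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d:
            d["synth"] = SynthConfig.from_dict(d["synth"])
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "cv" in d:
            d["cv"] = CVConfig(**d["cv"])
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)


@dataclass
class ModelRun:
    """One fitted model plus its provenance."""

    scope: str
    model: PLSDAModel
    selection: SelectionResult | None
    selected_idx: np.ndarray
    metrics_row: dict


@dataclass
class ExperimentReport:
    report: pd.DataFrame
    models: dict[str, ModelRun]
    frequency: FrequencyTable
    scan: pd.DataFrame
    best_threshold: int
    permutation: dict
    scores: dict[str, pd.DataFrame]
    manifest: dict


def _derived_seeds(master: int, n: int) -> list[int]:
    """Derive n reproducible sub-seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _model_row(
    scope: str, n: int, selected: np.ndarray, n_lv: int, metrics
) -> dict:
    return {
        "cohort": scope,
        "matrix": f"{n} × {selected.size}",
        "auc": round(metrics.auc, 4),
        "accuracy": round(metrics.accuracy, 4),
        "sensitivity": round(metrics.sensitivity, 4),
        "specificity": round(metrics.specificity, 4),
        "n_lv": n_lv,
        "n_variables": int(selected.size),
    }


def _fit_selected(
    table: PatientTable,
    selected: np.ndarray,
    config: RunConfig,
    cv: CVConfig,
    scope: str,
    selection: SelectionResult | None,
) -> ModelRun:
    xs = table.spectra[:, selected]
    y = table.coded_labels
    n_lv, _ = select_n_lvs(xs, y, config.max_lv, cv)
    res = cross_validate(xs, y, n_lv, cv)
    model = fit_pls(xs, y, n_lv)
    model.selected_variables = selected
    row = _model_row(scope, table.n_patients, selected, n_lv, res.metrics)
    return ModelRun(
        scope=scope,
        model=model,
        selection=selection,
        selected_idx=selected,
        metrics_row=row,
    )


def run_cohort_model(
    table: PatientTable, config: RunConfig, scope: str, cv_seed: int
) -> ModelRun:
    """Variable selection, LV tuning and cross-validated evaluation on
    one patient table."""
    if np.unique(table.label).size < 2:
        raise ValueError(f"{scope}: both classes must be present")
    cv = replace(config.cv, seed=cv_seed)
    selection = iterative_selection(
        table.spectra,
        table.coded_labels,
        cv,
        drop_fraction=config.drop_fraction,
        min_variables=config.min_variables,
        max_lv=config.max_lv,
    )
    return _fit_selected(table, selection.selected, config, cv, scope, selection)


def run_combined_model(
    table1: PatientTable,
    table2: PatientTable,
    config: RunConfig,
    seeds: list[int],
    sel1: SelectionResult | None = None,
    sel2: SelectionResult | None = None,
) -> tuple[dict[str, ModelRun], FrequencyTable, pd.DataFrame, int]:
    """The pooled-cohort arm: combined model, common-variables model
    and the stability/frequency-threshold model.

    ``seeds`` supplies [combined-cv, stability, scan-cv] seeds.  The
    common model keeps the intersection of the wavenumbers selected in
    cohort 1, cohort 2 and the pooled data; an empty intersection
    yields a flagged NaN row rather than an error.
    """
    if not np.array_equal(table1.wavenumbers, table2.wavenumbers):
        raise ValueError("cohorts must share one wavenumber grid")
    pooled = PatientTable(
        table1.wavenumbers,
        np.vstack([table1.spectra, table2.spectra]),
        np.concatenate([table1.patient_id, table2.patient_id]),
        np.concatenate([table1.label, table2.label]),
        np.concatenate([table1.cohort, table2.cohort]),
    )
    models: dict[str, ModelRun] = {}
    combined = run_cohort_model(pooled, config, "Dataset 1 + Dataset 2", seeds[0])
    models["combined"] = combined

    if sel1 is None:
        sel1 = run_cohort_model(table1, config, "Dataset 1", seeds[0]).selection
    if sel2 is None:
        sel2 = run_cohort_model(table2, config, "Dataset 2", seeds[0]).selection
    common = np.intersect1d(
        np.intersect1d(sel1.selected, sel2.selected), combined.selection.selected
    )
    cv = replace(config.cv, seed=seeds[0])
    if common.size == 0:
        row = {
            "cohort": "Dataset 1 + Dataset 2 in common",
            "matrix": f"{pooled.n_patients} × 0",
            "auc": np.nan,
            "accuracy": np.nan,
            "sensitivity": np.nan,
            "specificity": np.nan,
            "n_lv": 0,
            "n_variables": 0,
        }
        models["common"] = ModelRun(
            scope="Dataset 1 + Dataset 2 in common",
            model=None,
            selection=None,
            selected_idx=common,
            metrics_row=row,
        )
    else:
        models["common"] = _fit_selected(
            pooled, common, config, cv, "Dataset 1 + Dataset 2 in common", None
        )

    freq = stability_selection(
        pooled.spectra,
        pooled.coded_labels,
        config.cv,
        n_iter=config.stability_n_iter,
        holdout_per_class=config.holdout_per_class,
        seed=seeds[1],
        variable_ids=pooled.wavenumbers,
        drop_fraction=config.drop_fraction,
        min_variables=config.min_variables,
        max_lv=config.max_lv,
    )
    thresholds = np.array(
        sorted(t for t in set(config.thresholds) if t <= config.stability_n_iter)
    )
    cv_scan = replace(config.cv, seed=seeds[2])
    scan, best_thr = threshold_scan(
        pooled.spectra,
        pooled.coded_labels,
        freq,
        thresholds,
        cv_scan,
        max_lv=config.max_lv,
    )
    thr_selected = np.flatnonzero(freq.counts > best_thr)
    models["threshold"] = _fit_selected(
        pooled,
        thr_selected,
        config,
        cv_scan,
        f"Dataset 1 + Dataset 2 thr@{best_thr}",
        None,
    )
    return models, freq, scan, best_thr


def export_scores(model: PLSDAModel, table: PatientTable) -> pd.DataFrame:
    """Per-patient projection on the first two latent variables, with
    class and cohort labels, for score plots.  A one-LV model yields a
    table without the LV2 column."""
    idx = model.selected_variables
    x = table.spectra if idx is None else table.spectra[:, idx]
    t = transform(model, x)
    out = pd.DataFrame(
        {
            "patient_id": table.patient_id,
            "label": table.label,
            "cohort": table.cohort,
            "LV1": t[:, 0],
        }
    )
    if model.n_lv >= 2:
        out["LV2"] = t[:, 1]
    return out


def run_full_pipeline(
    config: RunConfig,
    outdir: str | Path | None = None,
    dataset: SpectralDataset | None = None,
) -> ExperimentReport:
    """Run the whole workflow and (optionally) write all artifacts.

    Stages, in fixed order: simulate (or take a provided raw dataset)
    -> preprocess every replicate -> average per patient -> per-cohort
    models -> pooled/common/threshold models -> permutation test of the
    threshold model -> report.  With identical config the report files
    are byte-identical across runs.
    """
    seeds = _derived_seeds(config.seed, 6)
    if dataset is None:
        dataset = generate_study(replace(config.synth, seed=seeds[0]))
    pre = preprocess_dataset(dataset, config.preprocess)
    patients = average_per_patient(pre)
    t1 = patients.subset(patients.cohort == 1)
    t2 = patients.subset(patients.cohort == 2)

    m1 = run_cohort_model(t1, config, "Dataset 1", seeds[1])
    m2 = run_cohort_model(t2, config, "Dataset 2", seeds[1])
    combo, freq, scan, best_thr = run_combined_model(
        t1, t2, config, seeds[2:5], sel1=m1.selection, sel2=m2.selection
    )
    models = {"dataset1": m1, "dataset2": m2, **combo}

    thr_run = models["threshold"]
    pooled_x = np.vstack([t1.spectra, t2.spectra])[:, thr_run.selected_idx]
    pooled_y = np.concatenate([t1.coded_labels, t2.coded_labels])
    perm = permutation_test(
        pooled_x,
        pooled_y,
        thr_run.model.n_lv,
        replace(config.cv, seed=seeds[4]),
        n_perm=config.n_permutations,
        metric="accuracy",
        seed=seeds[5],
    )
    perm_summary = {
        "metric": perm.metric,
        "observed": perm.observed_metric,
        "p_value": perm.p_value,
        "n_perm": perm.n_perm,
        "null_mean": float(perm.null_metrics.mean()),
        "null_max": float(perm.null_metrics.max()),
    }

    report = pd.DataFrame(
        [models[k].metrics_row for k in ("dataset1", "dataset2", "combined", "common", "threshold")],
        columns=REPORT_COLUMNS,
    )
    pooled_table = PatientTable(
        t1.wavenumbers,
        np.vstack([t1.spectra, t2.spectra]),
        np.concatenate([t1.patient_id, t2.patient_id]),
        np.concatenate([t1.label, t2.label]),
        np.concatenate([t1.cohort, t2.cohort]),
    )
    score_sources = {
        "dataset1": t1,
        "dataset2": t2,
        "combined": pooled_table,
        "threshold": pooled_table,
    }
    scores = {
        k: export_scores(models[k].model, tab)
        for k, tab in score_sources.items()
        if models[k].model is not None and models[k].model.n_lv >= 1
    }

    manifest = {
        "package_version": __version__,
        "stage_order": list(STAGE_ORDER),
        "config": config.to_dict(),
        "derived_seeds": seeds,
        "best_threshold": int(best_thr),
        "report_schema": REPORT_COLUMNS,
    }
    result = ExperimentReport(
        report=report,
        models=models,
        frequency=freq,
        scan=scan,
        best_threshold=best_thr,
        permutation=perm_summary,
        scores=scores,
        manifest=manifest,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: ExperimentReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(outdir / "report.csv", index=False)
    result.frequency.to_frame().to_csv(outdir / "frequency_table.csv", index=False)
    result.scan.to_csv(outdir / "threshold_scan.csv", index=False)
    for name, df in result.scores.items():
        df.to_csv(outdir / f"scores_{name}.csv", index=False)
    (outdir / "permutation.json").write_text(
        json.dumps(result.permutation, indent=2, sort_keys=True)
    )
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True)
    )


def nested_cv_metrics(
    table: PatientTable,
    config: RunConfig,
    n_outer: int = 5,
    seed: int = 0,
):
    """Fully nested evaluation: the variable selection and LV tuning
    are repeated inside every outer training split, so the outer
    predictions are untouched by any selection that saw the held-out
    patients.  Slower and typically less optimistic than the default
    selection-then-CV estimate."""
    from .plsda import _stratified_folds

    y = table.coded_labels
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, n_outer, rng, stratified=True)
    yhat = np.empty(table.n_patients)
    for k in range(n_outer):
        test = fold == k
        sub = table.subset(~test)
        run = run_cohort_model(sub, config, f"nested-fold{k}", int(rng.integers(2**31)))
        xs = table.spectra[test][:, run.selected_idx]
        yhat[test] = (xs - run.model.x_mean) @ run.model.b + run.model.y_mean
    return compute_metrics(y, yhat)
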