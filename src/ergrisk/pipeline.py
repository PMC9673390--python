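"""End-to-end orchestration: cohort -> split -> fit -> validate -> DCA -> trichotomy.

``run_full_pipeline`` reproduces the whole study workflow on one cohort:
an 80:20 stratified split, full and AIC-stepwise logistic models on the
training partition, internal validation (apparent and leave-one-out),
external validation on the test partition, decision curve analysis, and both
three-zone threshold methods.  One master seed drives dedicated substreams
for simulation and splitting, so every number in the report is recomputable
from the configuration alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dca import DecisionCurve, decision_curve
from .io import read_feature_table, write_feature_table
from .model import (
    LogisticModel,
    PredictionSet,
    fit_logistic,
    predict,
    split_data,
    stepwise_select,
)
from .simulate import COVARIATES, ERG_FEATURES, GeneratorConfig, generate_cohort
from .trichotomy import TrichotomyResult, trichotomize
from .validate import CalibrationReport, RocResult, accuracy_at, calibration_report, loocv, roc_auc

logger = logging.getLogger("ergrisk")

#: Full model scope: all eight ERG parameters plus age, sex and pupil size.
FULL_TERMS: tuple[str, ...] = (*ERG_FEATURES, *COVARIATES)


@dataclass
class PipelineConfig:
    """Settings of a full study run; defaults mirror the published analysis
    (80:20 split, TG-ROC level 0.90, uncertain-interval bound 0.55,
    DCA grid step 0.01, 10 Hosmer-Lemeshow bins)."""

    input: str | Path | GeneratorConfig | None = None
    split_ratio: float = 0.8
    seed: int = 0
    full_terms: tuple[str, ...] = FULL_TERMS
    tg_roc_theta: float = 0.90
    ui_max_sesp: float = 0.55
    dca_grid: float = 0.01
    dca_on: str = "test"
    hl_bins: int = 10
    run_loocv: bool = True
    output_dir: str | Path | None = None

    def config_hash(self) -> str:
        payload = {
            "input": str(self.input) if not isinstance(self.input, GeneratorConfig)
            else self.input.to_dict(),
            "split_ratio": self.split_ratio,
            "seed": self.seed,
            "full_terms": list(self.full_terms),
            "tg_roc_theta": self.tg_roc_theta,
            "ui_max_sesp": self.ui_max_sesp,
            "dca_grid": self.dca_grid,
            "dca_on": self.dca_on,
            "hl_bins": self.hl_bins,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyReport:
    """Everything the analysis computes, in one serializable object."""

    seed: int
    config_hash: str
    version: str
    n_train_case: int
    n_train_control: int
    n_test_case: int
    n_test_control: int
    full_model: LogisticModel
    best_model: LogisticModel
    internal_full: CalibrationReport
    internal_best: CalibrationReport
    internal_full_roc: RocResult
    internal_best_roc: RocResult
    internal_full_accuracy: float
    internal_best_accuracy: float
    loocv_report: CalibrationReport | None
    loocv_roc: RocResult | None
    loocv_accuracy: float | None
    external: CalibrationReport
    external_roc: RocResult
    external_accuracy: float
    dca: DecisionCurve
    dca_on: str
    tg_roc: TrichotomyResult
    uncertain_interval: TrichotomyResult

    def to_dict(self) -> dict:
        def opt(x):
            return x.to_dict() if x is not None else None

        return {
            "provenance": {
                "seed": self.seed,
                "config_hash": self.config_hash,
                "version": self.version,
            },
            "partitions": {
                "train": {"SMI": self.n_train_case, "control": self.n_train_control},
                "test": {"SMI": self.n_test_case, "control": self.n_test_control},
            },
            "models": {
                "full": self.full_model.to_dict(),
                "best": self.best_model.to_dict(),
            },
            "internal_validation": {
                "full": {
                    **self.internal_full.to_dict(),
                    "roc": self.internal_full_roc.to_dict(),
                    "accuracy": self.internal_full_accuracy,
                },
                "best": {
                    **self.internal_best.to_dict(),
                    "roc": self.internal_best_roc.to_dict(),
                    "accuracy": self.internal_best_accuracy,
                },
                "loocv": None if self.loocv_report is None else {
                    **self.loocv_report.to_dict(),
                    "roc": opt(self.loocv_roc),
                    "accuracy": self.loocv_accuracy,
                },
            },
            "external_validation": {
                **self.external.to_dict(),
                "roc": self.external_roc.to_dict(),
                "accuracy": self.external_accuracy,
            },
            "decision_curve": {**self.dca.to_dict(), "computed_on": self.dca_on},
            "trichotomy": {
                "tg_roc": self.tg_roc.to_dict(),
                "uncertain_interval": self.uncertain_interval.to_dict(),
            },
        }


def _substream_seeds(seed: int) -> dict[str, int]:
    """Independent integer seeds (< 2**31) for each stochastic stage."""
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "split")
    states = [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(len(names))]
    return dict(zip(names, states))


def load_cohort(config: PipelineConfig) -> pd.DataFrame:
    seeds = _substream_seeds(config.seed)
    src = config.input
    if src is None:
        from .simulate import reference_config

        gen = reference_config(seed=seeds["simulate"])
        return generate_cohort(gen)
    if isinstance(src, GeneratorConfig):
        return generate_cohort(src)
    return read_feature_table(src)


def run_full_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute every analysis stage in order; deterministic given the seed."""
    seeds = _substream_seeds(config.seed)
    table = load_cohort(config)

    logger.info("splitting cohort (ratio=%s)", config.split_ratio)
    train, test = split_data(table, ratio=config.split_ratio, seed=seeds["split"])

    logger.info("fitting full model (%d terms)", len(config.full_terms))
    full_terms = list(config.full_terms)
    full_model = fit_logistic(train, full_terms)
    logger.info("stepwise selection from the full model")
    best_model = stepwise_select(train, full_terms)
    null_model = fit_logistic(train, [])

    pred_train_full = predict(full_model, train)
    pred_train_best = predict(best_model, train)
    internal_full = calibration_report(
        pred_train_full, full_model, null_model, n_bins=config.hl_bins
    )
    internal_best = calibration_report(
        pred_train_best, best_model, null_model, n_bins=config.hl_bins
    )

    loocv_report = loocv_roc = loocv_acc = None
    if config.run_loocv:
        logger.info("leave-one-out cross-validation (%d folds)", len(train))
        pred_loocv = loocv(train, best_model.terms)
        loocv_report = calibration_report(pred_loocv, n_bins=config.hl_bins)
        loocv_roc = roc_auc(pred_loocv)
        loocv_acc = accuracy_at(pred_loocv)

    logger.info("external validation on the test partition")
    pred_test = predict(best_model, test)
    external = calibration_report(pred_test, n_bins=config.hl_bins)

    dca_pred = pred_test if config.dca_on == "test" else predict(best_model, train)
    curve = decision_curve(dca_pred, grid_step=config.dca_grid)

    tg = trichotomize(pred_test, method="tg-roc", theta=config.tg_roc_theta)
    ui = trichotomize(pred_test, method="ui", max_sesp=config.ui_max_sesp)

    report = StudyReport(
        seed=config.seed,
        config_hash=config.config_hash(),
        version=__version__,
        n_train_case=int((train["group"] == "SMI").sum()),
        n_train_control=int((train["group"] == "control").sum()),
        n_test_case=int((test["group"] == "SMI").sum()),
        n_test_control=int((test["group"] == "control").sum()),
        full_model=full_model,
        best_model=best_model,
        internal_full=internal_full,
        internal_best=internal_best,
        internal_full_roc=roc_auc(pred_train_full),
        internal_best_roc=roc_auc(pred_train_best),
        internal_full_accuracy=accuracy_at(pred_train_full),
        internal_best_accuracy=accuracy_at(pred_train_best),
        loocv_report=loocv_report,
        loocv_roc=loocv_roc,
        loocv_accuracy=loocv_acc,
        external=external,
        external_roc=roc_auc(pred_test),
        external_accuracy=accuracy_at(pred_test),
        dca=curve,
        dca_on=config.dca_on,
        tg_roc=tg,
        uncertain_interval=ui,
    )

    if config.output_dir is not None:
        _write_artifacts(report, train, test, Path(config.output_dir))
    return report


def _write_artifacts(
    report: StudyReport, train: pd.DataFrame, test: pd.DataFrame, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, default=float)
    )
    write_feature_table(train, outdir / "train.csv")
    write_feature_table(test, outdir / "test.csv")
    pd.DataFrame({
        "fpr": report.external_roc.fpr, "tpr": report.external_roc.tpr,
    }).to_csv(outdir / "roc_test.csv", index=False)
    pd.DataFrame(
        report.external.bins, columns=["mean_predicted", "observed", "count"]
    ).to_csv(outdir / "calibration_test.csv", index=False)
    pd.DataFrame({
        "pt": report.dca.thresholds,
        "nb_model": report.dca.nb_model,
        "nb_all": report.dca.nb_all,
        "nb_none": report.dca.nb_none,
    }).to_csv(outdir / "decision_curve.csv", index=False)
    logger.info("artifacts written to %s", outdir)
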