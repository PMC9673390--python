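"""Internal and external validation of the logistic risk model.

Covers the usual prediction-model report card: Brier score and Nagelkerke
pseudo-R2 for overall fit, the Hosmer-Lemeshow chi-square and risk-decile
calibration bins for calibration, leave-one-out cross-validation for
optimism, and the ROC curve with a DeLong confidence interval for
discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .model import LogisticModel, PredictionSet, fit_logistic, predict


@dataclass
class CalibrationReport:
    brier: float
    nagelkerke_r2: float | None
    hl_statistic: float
    hl_df: int
    hl_p: float
    bins: list[tuple[float, float, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "brier": self.brier,
            "nagelkerke_r2": self.nagelkerke_r2,
            "hl_statistic": self.hl_statistic,
            "hl_df": self.hl_df,
            "hl_p": self.hl_p,
            "bins": [list(b) for b in self.bins],
        }


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    ci_method: str = "delong"

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
        }


def brier_score(pred: PredictionSet) -> float:
    """Mean squared difference between predicted probability and outcome."""
    if len(pred) == 0:
        raise ValueError("empty prediction set")
    return float(np.mean((pred.p - pred.y_true) ** 2))


def nagelkerke_r2(model: LogisticModel, null_model: LogisticModel, n: int) -> float:
    """Cox-Snell likelihood-ratio R2 rescaled to its attainable maximum.

    ``R2_CS = 1 - exp(2 (L0 - L1) / n)`` divided by ``1 - exp(2 L0 / n)``,
    where L0/L1 are the intercept-only and fitted log-likelihoods.
    """
    l0, l1 = null_model.log_likelihood, model.log_likelihood
    if l1 < l0 - 1e-6:
        raise ValueError(
            "fitted log-likelihood below the null's: the models are not nested "
            "on the same data or a fit failed"
        )
    return _nagelkerke_from_llfs(l0, l1, n)


def _nagelkerke_from_llfs(l0: float, l1: float, n: int) -> float:
    cox_snell = 1.0 - np.exp(2.0 * (l0 - l1) / n)
    max_cs = 1.0 - np.exp(2.0 * l0 / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def nagelkerke_r2_from_predictions(pred: PredictionSet) -> float:
    """Nagelkerke R2 computed directly from a prediction set.

    The model log-likelihood is scored from the supplied probabilities and
    the null from the observed prevalence, which makes the statistic usable
    for out-of-fold (LOOCV) and external-validation predictions where no
    refit likelihood pair exists.
    """
    y, p = pred.y_true, pred.p
    l1 = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    pi = pred.prevalence
    if pi in (0.0, 1.0):
        raise ValueError("both classes must be present")
    l0 = float(len(pred) * (pi * np.log(pi) + (1 - pi) * np.log1p(-pi)))
    return _nagelkerke_from_llfs(l0, max(l1, l0), len(pred))


def _risk_bins(pred: PredictionSet, n_bins: int) -> pd.DataFrame:
    """Quantile bins of predicted risk; ties share a bin (so bins can merge)."""
    df = pd.DataFrame({"y": pred.y_true, "p": pred.p})
    df["bin"] = pd.qcut(df["p"].rank(method="first"), q=n_bins, labels=False,
                        duplicates="drop")
    # rows with identical p must share a bin: reassign by the bin of the
    # first occurrence of each distinct probability
    first_bin = df.groupby("p")["bin"].transform("min")
    df["bin"] = first_bin
    grouped = df.groupby("bin").agg(
        observed=("y", "sum"), expected=("p", "sum"),
        mean_p=("p", "mean"), count=("y", "size"),
    )
    return grouped.reset_index(drop=True)


def calibration_bins(
    pred: PredictionSet, n_bins: int = 10
) -> list[tuple[float, float, int]]:
    """Per-risk-decile (mean predicted, observed proportion, count) triples."""
    g = _risk_bins(pred, n_bins)
    return [
        (float(r.mean_p), float(r.observed / r.count), int(r.count))
        for r in g.itertuples()
    ]


def hosmer_lemeshow(
    pred: PredictionSet, n_bins: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit test on risk-quantile bins.

    Returns ``(statistic, df, p)`` with ``df = bins - 2`` (the reference
    distribution for probabilities fitted on the same data).  Bins whose
    expected event or non-event count is ~0 are merged with their neighbour
    so the statistic never divides by zero.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if len(pred) < n_bins:
        raise ValueError("need at least one subject per requested bin")
    g = _risk_bins(pred, n_bins)
    # merge bins with vanishing expected events or non-events into neighbours
    rows = g.to_dict("records")
    merged = True
    while merged and len(rows) > 1:
        merged = False
        for i, row in enumerate(rows):
            e1 = row["expected"]
            e0 = row["count"] - row["expected"]
            if e1 < 1e-9 or e0 < 1e-9:
                j = i - 1 if i > 0 else i + 1
                keep = rows[j]
                keep["observed"] += row["observed"]
                keep["expected"] += row["expected"]
                keep["mean_p"] = (
                    keep["mean_p"] * keep["count"] + row["mean_p"] * row["count"]
                ) / (keep["count"] + row["count"])
                keep["count"] += row["count"]
                del rows[i]
                merged = True
                break
    stat = 0.0
    for row in rows:
        e1 = row["expected"]
        e0 = row["count"] - row["expected"]
        o1 = row["observed"]
        o0 = row["count"] - row["observed"]
        if e1 > 1e-9:
            stat += (o1 - e1) ** 2 / e1
        if e0 > 1e-9:
            stat += (o0 - e0) ** 2 / e0
    df = len(rows) - 2
    p = float(stats.chi2.sf(stat, df)) if df >= 1 else 1.0
    return float(stat), df, p


def loocv(table: pd.DataFrame, terms: list[str]) -> PredictionSet:
    """Leave-one-out cross-validation with a fixed term set.

    Each subject's probability comes from a model refit on the other n-1
    subjects, so the pooled predictions are free of apparent-performance
    optimism.  A non-convergent fold aborts the run by default.
    """
    n = len(table)
    if n < len(terms) + 3:
        raise ValueError("too few subjects for leave-one-out with this term set")
    probs = np.empty(n)
    labels = np.empty(n, dtype=int)
    for i in range(n):
        rest = table.drop(table.index[i])
        fold_model = fit_logistic(rest, terms)
        if not fold_model.converged:
            raise RuntimeError(
                f"LOOCV fold {i} did not converge: {fold_model.diagnostic}"
            )
        row = table.iloc[[i]]
        ps = predict(fold_model, row)
        probs[i] = ps.p[0]
        labels[i] = ps.y_true[0]
    return PredictionSet(y_true=labels, p=probs)


def _delong_auc_variance(pred: PredictionSet) -> tuple[float, float]:
    """AUC and its DeLong variance via midrank placements."""
    pos = pred.p[pred.y_true == 1]
    neg = pred.p[pred.y_true == 0]
    m, n = len(pos), len(neg)
    allscores = np.concatenate([pos, neg])
    rank_all = stats.rankdata(allscores)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    # placements: V10_i = P(score_i > random control) with ties at 1/2
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    auc = float(v10.mean())
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n if m > 1 and n > 1 else 0.0
    return auc, float(var)


def roc_auc(pred: PredictionSet, alpha: float = 0.05) -> RocResult:
    """Empirical ROC curve with trapezoidal AUC and DeLong Wald CI.

    The AUC equals the tie-corrected Mann-Whitney statistic: the probability
    that a random case outscores a random control, ties counting one half.
    """
    if len(np.unique(pred.y_true)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(pred.y_true, pred.p)
    auc, var = _delong_auc_variance(pred)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        ci_method="delong",
    )


def accuracy_at(pred: PredictionSet, threshold: float = 0.5) -> float:
    """Fraction correctly classified under the half-open rule p >= t => positive.

    A threshold above every probability therefore classifies everyone
    negative (accuracy = prevalence of controls); a threshold of 0 classifies
    everyone positive.
    """
    positive = pred.p >= threshold
    return float(np.mean(positive == (pred.y_true == 1)))


def calibration_report(
    pred: PredictionSet,
    model: LogisticModel | None = None,
    null_model: LogisticModel | None = None,
    n_bins: int = 10,
) -> CalibrationReport:
    """Bundle Brier, Nagelkerke R2 (when both models are given), HL test and
    calibration bins into one report."""
    stat, df, p = hosmer_lemeshow(pred, n_bins=n_bins)
    if model is not None and null_model is not None:
        r2 = nagelkerke_r2(model, null_model, n=len(pred))
    else:
        r2 = nagelkerke_r2_from_predictions(pred)
    return CalibrationReport(
        brier=brier_score(pred),
        nagelkerke_r2=r2,
        hl_statistic=stat,
        hl_df=df,
        hl_p=p,
        bins=calibration_bins(pred, n_bins=n_bins),
    )
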