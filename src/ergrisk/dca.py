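"""Decision curve analysis: net benefit of acting on the model's predictions.

At a threshold probability ``pt`` — the risk at which a decision-maker is
indifferent between intervening and not — the net benefit of a prediction
rule is

    NB(pt) = TP/n - (FP/n) * pt / (1 - pt)

where subjects with predicted probability >= pt are treated as positive.
The model is compared against the two extreme strategies: treat-all
(NB = prevalence - (1 - prevalence) * pt/(1-pt)) and treat-none (NB = 0).
The superiority range is the widest contiguous threshold interval on which
the model's curve is at least as good as both comparators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PredictionSet

_TOL = 1e-12


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    superior_range: tuple[float, float] | None
    n: int
    prevalence: float

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "nb_model": self.nb_model.tolist(),
            "nb_all": self.nb_all.tolist(),
            "nb_none": self.nb_none.tolist(),
            "superior_range": list(self.superior_range) if self.superior_range else None,
            "n": self.n,
            "prevalence": self.prevalence,
        }


def _check_pt(pt: float) -> None:
    if not 0.0 < pt < 1.0:
        raise ValueError(f"threshold probability must lie in (0, 1), got {pt}")


def net_benefit(pred: PredictionSet, pt: float) -> float:
    """Net benefit of the model's rule ``p >= pt`` at threshold ``pt``."""
    _check_pt(pt)
    positive = pred.p >= pt
    n = len(pred)
    tp = int(np.sum(positive & (pred.y_true == 1)))
    fp = int(np.sum(positive & (pred.y_true == 0)))
    return tp / n - (fp / n) * pt / (1.0 - pt)


def treat_all_benefit(prevalence: float, pt: float) -> float:
    """Net benefit of intervening on everyone (all controls are false
    positives); crosses zero exactly at pt = prevalence."""
    _check_pt(pt)
    return prevalence - (1.0 - prevalence) * pt / (1.0 - pt)


def decision_curve(pred: PredictionSet, grid_step: float = 0.01) -> DecisionCurve:
    """Evaluate model, treat-all and treat-none net benefit on a pt grid.

    The default grid is 0.01..0.99 in steps of 0.01 (99 thresholds).
    """
    if len(pred) == 0 or len(np.unique(pred.y_true)) < 2:
        raise ValueError("predictions must be non-empty with both classes present")
    k = int(round(1.0 / grid_step)) - 1
    grid = np.round(np.arange(1, k + 1) * grid_step, 12)
    grid = grid[(grid > 0.0) & (grid < 1.0)]
    prevalence = pred.prevalence
    nb_model = np.array([net_benefit(pred, pt) for pt in grid])
    nb_all = np.array([treat_all_benefit(prevalence, pt) for pt in grid])
    nb_none = np.zeros_like(grid)
    curve = DecisionCurve(
        thresholds=grid,
        nb_model=nb_model,
        nb_all=nb_all,
        nb_none=nb_none,
        superior_range=None,
        n=len(pred),
        prevalence=prevalence,
    )
    curve.superior_range = superior_range(curve)
    return curve


def superior_range(curve: DecisionCurve) -> tuple[float, float] | None:
    """Widest contiguous grid interval where the model's net benefit is at
    least the better comparator's, with strict superiority somewhere inside.

    Equality plateaus therefore do not fragment the range, but an interval
    that never strictly beats both comparators does not count.
    """
    comparator = np.maximum(curve.nb_all, 0.0)
    ok = curve.nb_model >= comparator - _TOL
    strict = curve.nb_model > comparator + _TOL
    best: tuple[float, float] | None = None
    best_len = 0
    i = 0
    m = len(curve.thresholds)
    while i < m:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and ok[j + 1]:
            j += 1
        if strict[i : j + 1].any() and (j - i + 1) > best_len:
            best = (float(curve.thresholds[i]), float(curve.thresholds[j]))
            best_len = j - i + 1
        i = j + 1
    return best
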