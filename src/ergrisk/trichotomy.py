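"""Three-zone decision thresholds: most likely SMI / uncertain / most likely not.

Instead of a single probability cutoff, two cutoffs ``t_low <= t_high`` carve
the model's score range into a certain-negative zone (score < t_low), an
uncertain zone (t_low <= score <= t_high, closed interval) and a
certain-positive zone (score > t_high).  Sensitivity, specificity and
accuracy are then scored on the certain zones only, from the 3x2 table
cells::

                      SMI   control
    certain positive   a       b
    uncertain         u1      u0
    certain negative   c       d

    sensitivity = a / (a + c)
    specificity = d / (b + d)
    accuracy    = (a + d) / (a + b + c + d)

Two cutoff-selection methods are provided:

* **TG-ROC** (two-graph ROC): plot sensitivity and specificity against the
  threshold; ``t_low`` is the largest threshold keeping Se >= theta and
  ``t_high`` the smallest keeping Sp >= theta (theta = 0.90 by default).
* **Uncertain interval**: locate the score ``x*`` where the case and control
  score densities intersect, then search all candidate interval pairs
  enclosing ``x*`` for the largest interval whose within-interval sensitivity
  and specificity (dichotomized at ``x*``) are both at or below a near-chance
  bound (0.55 by default) — the scores too ambiguous to act on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import PredictionSet


@dataclass
class TrichotomyResult:
    """Two cutoffs, the 3x2 table cells, and certain-zone accuracy measures."""

    method: str
    t_low: float
    t_high: float
    a: int
    b: int
    u_case: int
    u_control: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if self.t_low > self.t_high:
            raise ValueError("t_low must not exceed t_high")

    @property
    def n(self) -> int:
        return self.a + self.b + self.u_case + self.u_control + self.c + self.d

    @property
    def n_uncertain(self) -> int:
        return self.u_case + self.u_control

    @property
    def sensitivity(self) -> float:
        """a / (a + c); NaN when no case falls in a certain zone."""
        return self.a / (self.a + self.c) if self.a + self.c else float("nan")

    @property
    def specificity(self) -> float:
        """d / (b + d); NaN when no control falls in a certain zone."""
        return self.d / (self.b + self.d) if self.b + self.d else float("nan")

    @property
    def accuracy(self) -> float:
        denom = self.a + self.b + self.c + self.d
        return (self.a + self.d) / denom if denom else float("nan")

    @classmethod
    def from_cells(
        cls, a: int, b: int, u_case: int, u_control: int, c: int, d: int,
        t_low: float = 0.0, t_high: float = 1.0, method: str = "cells",
    ) -> "TrichotomyResult":
        return cls(method=method, t_low=t_low, t_high=t_high,
                   a=a, b=b, u_case=u_case, u_control=u_control, c=c, d=d)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "t_low": self.t_low,
            "t_high": self.t_high,
            "cells": {"a": self.a, "b": self.b, "u_case": self.u_case,
                      "u_control": self.u_control, "c": self.c, "d": self.d},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "n_uncertain": self.n_uncertain,
        }


class Thresholds(NamedTuple):
    t_low: float
    t_high: float
    collapsed: bool = False
    warning: str = ""


def se_sp_profile(pred: PredictionSet) -> pd.DataFrame:
    """Sensitivity and specificity at every distinct score, plus sentinels.

    Under the rule ``p >= t => positive``, Se is non-increasing and Sp
    non-decreasing in t.  Sentinel thresholds just below the minimum and just
    above the maximum score give the (Se=1, Sp=0) and (Se=0, Sp=1) endpoints.
    """
    y, p = pred.y_true, pred.p
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    scores = np.unique(p)
    thresholds = np.concatenate((
        [np.nextafter(scores[0], -np.inf)],
        scores,
        [np.nextafter(scores[-1], np.inf)],
    ))
    n_case = int((y == 1).sum())
    n_control = int((y == 0).sum())
    se = [(p[y == 1] >= t).sum() / n_case for t in thresholds]
    sp = [(p[y == 0] < t).sum() / n_control for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "se": se, "sp": sp})


def tg_roc_thresholds(pred: PredictionSet, theta: float = 0.90) -> Thresholds:
    """TG-ROC cutoffs at a preselected sensitivity and specificity level.

    ``t_low`` is the largest threshold with Se >= theta, ``t_high`` the
    smallest with Sp >= theta.  Candidate thresholds are the observed scores
    plus midpoints of consecutive scores (no interpolation of Se/Sp: the
    conservative step rule).  If the score distributions are separated enough
    that ``t_low > t_high``, both collapse to the Se = Sp crossing point and
    the uncertain zone is empty.
    """
    if not 0.5 < theta <= 1.0:
        raise ValueError("theta must lie in (0.5, 1]")
    y, p = pred.y_true, pred.p
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    grid = _candidate_grid(p)
    thresholds = np.concatenate((
        [np.nextafter(grid[0], -np.inf)], grid, [np.nextafter(grid[-1], np.inf)]
    ))
    se = np.array([(p[y == 1] >= t).mean() for t in thresholds])
    sp = np.array([(p[y == 0] < t).mean() for t in thresholds])
    prof = pd.DataFrame({"threshold": thresholds, "se": se, "sp": sp})
    se_ok = prof[prof["se"] >= theta]
    sp_ok = prof[prof["sp"] >= theta]
    warning = ""
    # the sentinel endpoints guarantee both sets are non-empty
    t_low = float(se_ok["threshold"].max())
    t_high = float(sp_ok["threshold"].min())
    if se_ok["threshold"].max() == prof["threshold"].iloc[0]:
        warning = f"Se >= {theta} only attainable at the all-positive sentinel"
    if sp_ok["threshold"].min() == prof["threshold"].iloc[-1]:
        warning = f"Sp >= {theta} only attainable at the all-negative sentinel"
    if t_low > t_high:
        gap = prof["se"] - prof["sp"]
        cross = int(np.abs(gap.to_numpy()).argmin())
        t = float(prof["threshold"].iloc[cross])
        return Thresholds(t, t, collapsed=True, warning=warning)
    return Thresholds(t_low, t_high, collapsed=False, warning=warning)


def intersection_point(pred: PredictionSet) -> float:
    """Score at which the case and control score densities are equal.

    Densities are Gaussian-kernel estimates (Silverman bandwidth).  Among
    multiple crossings, the one between the group medians is preferred
    (closest to their midpoint); with no crossing at all — degenerate or
    identical distributions — the pooled median is returned.
    """
    pos = pred.p[pred.y_true == 1]
    neg = pred.p[pred.y_true == 0]
    if len(np.unique(pos)) < 2 or len(np.unique(neg)) < 2:
        raise ValueError("constant scores within a group: no density to intersect")
    kde_pos = stats.gaussian_kde(pos, bw_method="silverman")
    kde_neg = stats.gaussian_kde(neg, bw_method="silverman")

    med_pos, med_neg = np.median(pos), np.median(neg)
    mid = 0.5 * (med_pos + med_neg)
    lo = min(pred.p.min(), med_neg, med_pos)
    hi = max(pred.p.max(), med_neg, med_pos)
    grid = np.linspace(lo, hi, 512)
    diff = kde_pos(grid) - kde_neg(grid)
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if len(sign_change) == 0:
        return float(np.median(pred.p))
    roots = []
    for i in sign_change:
        root = optimize.brentq(
            lambda x: kde_pos(x)[0] - kde_neg(x)[0], grid[i], grid[i + 1]
        )
        roots.append(root)
    roots = np.asarray(roots)
    lo_med, hi_med = min(med_pos, med_neg), max(med_pos, med_neg)
    between = roots[(roots >= lo_med) & (roots <= hi_med)]
    pool = between if len(between) else roots
    return float(pool[np.argmin(np.abs(pool - mid))])


def _candidate_grid(scores: np.ndarray) -> np.ndarray:
    """Observed distinct scores plus midpoints of consecutive pairs."""
    s = np.unique(scores)
    if len(s) == 1:
        return s
    mids = (s[:-1] + s[1:]) / 2.0
    return np.unique(np.concatenate([s, mids]))


def uncertain_interval(
    pred: PredictionSet,
    max_sesp: float = 0.55,
    intersection: float | None = None,
) -> Thresholds:
    """Uncertain-interval cutoffs around the density intersection.

    Candidate cutoff pairs ``(t_low <= x* <= t_high)`` are drawn from the
    observed score grid (scores plus midpoints).  For each pair, sensitivity
    and specificity are computed among the subjects whose scores fall inside
    the closed interval, dichotomized at ``x*``; among pairs with both at or
    below ``max_sesp``, the pair enclosing the most subjects wins (ties:
    narrower interval, then lower ``t_low``).  With no qualifying pair the
    interval is empty: ``t_low = t_high = x*`` with a warning flag.
    """
    if not 0.5 < max_sesp < 1.0:
        raise ValueError("max_sesp must lie in (0.5, 1)")
    x_star = intersection_point(pred) if intersection is None else intersection
    p, y = pred.p, pred.y_true
    grid = _candidate_grid(p)
    lows = grid[grid <= x_star]
    highs = grid[grid >= x_star]

    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    cum_case = np.concatenate([[0], np.cumsum(ys == 1)])
    cum_ctrl = np.concatenate([[0], np.cumsum(ys == 0)])

    # counts inside the closed interval [lo, hi], dichotomized at x_star
    # (below x_star => predicted negative), vectorized over all pairs
    i_idx = np.searchsorted(ps, lows, side="left")[:, None]
    j_idx = np.searchsorted(ps, highs, side="right")[None, :]
    k_idx = np.clip(np.searchsorted(ps, x_star, side="left"), i_idx, j_idx)
    fn = cum_case[k_idx] - cum_case[i_idx]
    tn = cum_ctrl[k_idx] - cum_ctrl[i_idx]
    tp = cum_case[j_idx] - cum_case[k_idx]
    fp = cum_ctrl[j_idx] - cum_ctrl[k_idx]
    n_case_in = tp + fn
    n_ctrl_in = tn + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        se_u = np.where(n_case_in > 0, tp / np.maximum(n_case_in, 1), np.nan)
        sp_u = np.where(n_ctrl_in > 0, tn / np.maximum(n_ctrl_in, 1), np.nan)
    qualifies = (
        (n_case_in > 0) & (n_ctrl_in > 0)
        & (se_u <= max_sesp) & (sp_u <= max_sesp)
    )
    if not qualifies.any():
        return Thresholds(float(x_star), float(x_star), collapsed=True,
                          warning="no interval satisfies the Se/Sp bound")
    # lexicographic choice: most enclosed subjects, then narrower, then lower
    enclosed = n_case_in + n_ctrl_in
    width = highs[None, :] - lows[:, None]
    pick = qualifies & (enclosed == enclosed[qualifies].max())
    pick &= width == width[pick].min()
    rows, cols = np.nonzero(pick)
    best_row = rows[np.argmin(lows[rows])]
    best_col = cols[rows == best_row][0]
    return Thresholds(float(lows[best_row]), float(highs[best_col]))


def trichotomy_table(
    pred: PredictionSet, t_low: float, t_high: float, method: str = "custom"
) -> TrichotomyResult:
    """Assign subjects to the three zones and fill the 3x2 table.

    Certain-positive means score > t_high; certain-negative means score
    < t_low; the uncertain zone is the closed interval [t_low, t_high].
    """
    if t_low > t_high:
        raise ValueError("t_low must not exceed t_high")
    p, y = pred.p, pred.y_true
    pos_zone = p > t_high
    neg_zone = p < t_low
    unc_zone = ~pos_zone & ~neg_zone
    return TrichotomyResult(
        method=method,
        t_low=float(t_low),
        t_high=float(t_high),
        a=int(np.sum(pos_zone & (y == 1))),
        b=int(np.sum(pos_zone & (y == 0))),
        u_case=int(np.sum(unc_zone & (y == 1))),
        u_control=int(np.sum(unc_zone & (y == 0))),
        c=int(np.sum(neg_zone & (y == 1))),
        d=int(np.sum(neg_zone & (y == 0))),
    )


def trichotomize(
    pred: PredictionSet,
    method: str = "tg-roc",
    theta: float = 0.90,
    max_sesp: float = 0.55,
) -> TrichotomyResult:
    """Select cutoffs by the named method and score the resulting table."""
    if method in ("tg-roc", "tgroc"):
        thr = tg_roc_thresholds(pred, theta=theta)
        name = "TG-ROC"
    elif method in ("uncertain-interval", "ui"):
        thr = uncertain_interval(pred, max_sesp=max_sesp)
        name = "uncertain-interval"
    else:
        raise ValueError(f"unknown trichotomization method {method!r}")
    return trichotomy_table(pred, thr.t_low, thr.t_high, method=name)
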