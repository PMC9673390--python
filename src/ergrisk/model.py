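"""Model development: stratified splitting, logistic fits, AIC stepwise selection.

The risk model is an ordinary maximum-likelihood logistic regression of
case-control status (SMI = 1, control = 0) on a subset of the eight cone ERG
parameters plus age, sex and pupil size.  Term selection mimics the classical
bidirectional stepwise search: start from the full model and repeatedly take
the single-term deletion or re-addition that lowers the AIC most, stopping at
a local AIC optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

#: Probabilities are clipped to [PROB_EPS, 1 - PROB_EPS] so that downstream
#: log-likelihood based metrics stay finite under (quasi-)separation.
PROB_EPS = 1e-10

#: A coefficient whose magnitude exceeds this on the standardized scale
#: (|beta| * SD(x)) is treated as evidence of separation.
SEPARATION_BOUND = 15.0

_CONVERGENCE_TOL = 1e-8
_MAX_ITER = 100


class RankDeficientDesignError(ValueError):
    """Raised when the design matrix is collinear; names the offending terms."""


@dataclass
class LogisticModel:
    """A fitted logistic risk model on the log-odds scale."""

    terms: list[str]
    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    aic: float
    n_fit: int
    converged: bool
    diagnostic: str = ""

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "standard_errors": dict(self.standard_errors),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_fit": self.n_fit,
            "converged": self.converged,
            "diagnostic": self.diagnostic,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LogisticModel":
        return cls(**data)


@dataclass
class PredictionSet:
    """Paired true labels (SMI = 1) and predicted probabilities."""

    y_true: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=int)
        self.p = np.clip(np.asarray(self.p, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
        if self.y_true.shape != self.p.shape:
            raise ValueError("labels and probabilities must have equal length")
        if not np.isin(self.y_true, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.y_true)

    @property
    def prevalence(self) -> float:
        return float(self.y_true.mean())


def outcome_vector(table: pd.DataFrame) -> np.ndarray:
    return (table["group"] == "SMI").to_numpy(dtype=float)


def design_matrix(table: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Numeric design matrix (no intercept column); sex coded male = 1."""
    cols = {}
    for term in terms:
        if term not in table.columns:
            raise KeyError(f"model term {term!r} not present in the table")
        if term == "sex":
            cols[term] = (table[term] == "male").astype(float).to_numpy()
        else:
            cols[term] = pd.to_numeric(table[term]).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=table.index)


def split_data(
    table: pd.DataFrame, ratio: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-stratified random split into train and test partitions.

    Per group, the training share is ``round(ratio * group size)`` (half-up),
    which reproduces the published 241/160 vs 60/40 partition for 301 cases
    and 200 controls at an 80:20 ratio.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for label in ("SMI", "control"):
        idx = table.index[table["group"] == label].to_numpy()
        if len(idx) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 members; cannot stratify")
        perm = rng.permutation(idx)
        n_train = int(np.floor(ratio * len(idx) + 0.5))
        train_parts.append(table.loc[perm[:n_train]])
        test_parts.append(table.loc[perm[n_train:]])
    train = pd.concat(train_parts).sort_index().reset_index(drop=True)
    test = pd.concat(test_parts).sort_index().reset_index(drop=True)
    return train, test


def _check_rank(X: pd.DataFrame) -> None:
    if X.shape[1] == 0:
        return
    arr = np.column_stack([np.ones(len(X)), X.to_numpy()])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # locate collinear columns via pivoted QR on standardized columns
        std = X.to_numpy() - X.to_numpy().mean(axis=0)
        norms = np.linalg.norm(std, axis=0)
        norms[norms == 0] = 1.0
        r = np.linalg.qr(std / norms, mode="r")
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] < 1e-8]
        bad = bad or list(X.columns)
        raise RankDeficientDesignError(
            f"design matrix is rank deficient; collinear terms: {bad}"
        )


def fit_logistic(table: pd.DataFrame, terms: list[str]) -> LogisticModel:
    """Maximum-likelihood logistic fit of SMI status on ``terms``.

    Fitting is IRLS (statsmodels GLM, binomial family) with a deviance-change
    tolerance of 1e-8 and at most 100 iterations.  Perfect or
    quasi-perfect separation is flagged (``converged=False`` with a
    diagnostic) rather than silently returned; a rank-deficient design
    raises :class:`RankDeficientDesignError` naming the collinear terms.
    """
    y = outcome_vector(table)
    X = design_matrix(table, list(terms))
    _check_rank(X)
    exog = sm.add_constant(X, has_constant="add")

    separation_flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, exog, family=sm.families.Binomial()).fit(
            maxiter=_MAX_ITER, tol=_CONVERGENCE_TOL
        )
        for w in caught:
            if issubclass(w.category, PerfectSeparationWarning):
                separation_flagged = True

    params = res.params
    bse = res.bse
    llf = float(res.llf)
    k = len(params)
    aic = -2.0 * llf + 2.0 * k

    # separation also shows as diverging standardized coefficients
    sds = X.std(ddof=0).replace(0.0, 1.0) if len(terms) else pd.Series(dtype=float)
    for term in terms:
        if abs(params[term]) * float(sds[term]) > SEPARATION_BOUND:
            separation_flagged = True

    converged = bool(getattr(res, "converged", True)) and not separation_flagged
    diagnostic = ""
    if separation_flagged:
        diagnostic = "possible separation: diverging coefficients detected"
    elif not converged:
        diagnostic = f"IRLS did not converge in {_MAX_ITER} iterations"

    return LogisticModel(
        terms=list(terms),
        intercept=float(params["const"]),
        coefficients={t: float(params[t]) for t in terms},
        standard_errors={t: float(bse[t]) for t in terms},
        log_likelihood=llf,
        aic=aic,
        n_fit=len(table),
        converged=converged,
        diagnostic=diagnostic,
    )


def predict(model: LogisticModel, table: pd.DataFrame) -> PredictionSet:
    """Apply a fitted model: probabilities are the inverse-logit of the
    linear predictor, paired with the table's true labels."""
    X = design_matrix(table, model.terms)
    eta = model.intercept + sum(
        model.coefficients[t] * X[t].to_numpy() for t in model.terms
    )
    eta = np.asarray(eta, dtype=float) if model.terms else np.full(len(table), model.intercept)
    prob = 1.0 / (1.0 + np.exp(-eta))
    return PredictionSet(y_true=outcome_vector(table).astype(int), p=prob)


def stepwise_select(
    table: pd.DataFrame, full_terms: list[str], tol: float = 1e-9
) -> LogisticModel:
    """Bidirectional AIC-stepwise selection starting from the full model.

    At each step every single-term deletion from the current model and every
    re-addition from ``full_terms`` is scored; the move with the lowest AIC
    is taken if it improves on the current AIC, otherwise the search stops.
    Ties break toward the earliest candidate in input order, which makes the
    procedure deterministic.  The selected model's AIC never exceeds the full
    model's because the search starts there.
    """
    full_terms = list(full_terms)
    if len(set(full_terms)) != len(full_terms):
        raise ValueError("full_terms contains duplicate entries")
    current = fit_logistic(table, full_terms)
    while True:
        best_move: LogisticModel | None = None
        candidates: list[list[str]] = []
        candidates.extend(
            [t for t in current.terms if t != drop] for drop in current.terms
        )
        candidates.extend(
            current.terms + [add] for add in full_terms if add not in current.terms
        )
        for cand in candidates:
            fit = fit_logistic(table, cand)
            if best_move is None or fit.aic < best_move.aic - tol:
                best_move = fit
        if best_move is not None and best_move.aic < current.aic - tol:
            current = best_move
        else:
            return current
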