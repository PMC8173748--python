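"""Logistic response modeling: univariate screening, backward stepwise
selection, odds ratios with Wald intervals, model ROC, and leave-one-out
cross-validated classification metrics.

Continuous imaging predictors are first dichotomized at their
Youden-optimal cutpoints (:func:`dichotomize`); candidate variables with
univariate p < 0.05 enter a backward stepwise logistic regression that
iteratively removes the variable with the largest Wald p >= 0.05.
Maximum likelihood fitting is delegated to statsmodels; complete
separation is detected and flagged, never silently regularized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import ConfigurationError, InsufficientDataError
from .stats import RocResult, roc

_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class LogisticModel:
    """A fitted (unpenalized) logistic regression for pCR.

    ``odds_ratios`` maps variable -> (OR, CI low, CI high); odds ratios
    are exp(coefficient) with Wald 95% intervals exp(coef +/- 1.96 SE).
    """

    variables: tuple[str, ...]
    coefficients: Mapping[str, float]
    std_errors: Mapping[str, float]
    odds_ratios: Mapping[str, tuple[float, float, float]]
    p_values: Mapping[str, float]
    intercept: float
    converged: bool
    separation: bool
    fitted_probabilities: np.ndarray
    log_likelihood: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior pCR probability for new rows (same columns)."""
        eta = np.full(len(X), self.intercept, dtype=float)
        for var in self.variables:
            eta += self.coefficients[var] * X[var].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


@dataclass(frozen=True)
class CvMetrics:
    """Leave-one-out classification metrics at a probability cutoff."""

    sensitivity: float
    specificity: float
    accuracy: float
    predictions: pd.DataFrame  # per-fold held-out probabilities and calls
    n_skipped: int = 0

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity, self.accuracy):
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError("metrics must lie in [0, 1]")


# ---------------------------------------------------------------------------
# operations


def dichotomize(
    values: Sequence[float],
    threshold: float,
    direction: str = "above",
) -> np.ndarray:
    """Binary-code a feature at a cutpoint.

    ``direction='above'``: 1 when value > threshold (reference is the
    <= branch); ``direction='at_or_below'``: 1 when value <= threshold.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(threshold):
        raise ConfigurationError("threshold must be finite")
    if direction == "above":
        return (x > threshold).astype(int)
    if direction == "at_or_below":
        return (x <= threshold).astype(int)
    raise ConfigurationError(f"unknown direction {direction!r}")


def _detect_separation(probs: np.ndarray, y: np.ndarray) -> bool:
    """Complete separation: every fitted probability at its label."""
    return bool(np.all(np.abs(probs - y) < 1e-6))


def fit_logistic(X: pd.DataFrame, y: Sequence[int]) -> LogisticModel:
    """Maximum-likelihood logistic fit with Wald odds-ratio intervals.

    Raises on degenerate inputs; on (quasi-)separation the fit is
    retried with a capped quasi-Newton optimizer and flagged.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if len(X) != y.size:
        raise InsufficientDataError("design and outcome lengths differ")
    if len(set(y)) < 2:
        raise InsufficientDataError("outcome must contain both classes")
    if len(X) <= X.shape[1] + 1:
        raise InsufficientDataError("need n greater than the parameter count")

    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, method="newton")
            converged = bool(res.mle_retvals.get("converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=300, method="bfgs")
            separation = True
            converged = False
    probs = np.asarray(res.predict(Xc), dtype=float)
    if _detect_separation(probs, y):
        separation = True
    params = res.params
    bse = res.bse
    pvals = res.pvalues
    variables = tuple(c for c in Xc.columns if c != "const")
    odds = {}
    with np.errstate(over="ignore"):
        for v in variables:
            lo = float(np.exp(params[v] - _Z95 * bse[v]))
            hi = float(np.exp(params[v] + _Z95 * bse[v]))
            odds[v] = (float(np.exp(params[v])), lo, hi)
    return LogisticModel(
        variables=variables,
        coefficients={v: float(params[v]) for v in variables},
        std_errors={v: float(bse[v]) for v in variables},
        odds_ratios=odds,
        p_values={v: float(pvals[v]) for v in variables},
        intercept=float(params["const"]),
        converged=converged,
        separation=separation,
        fitted_probabilities=np.clip(probs, 1e-12, 1 - 1e-12),
        log_likelihood=float(res.llf),
    )


def backward_stepwise(
    X: pd.DataFrame,
    y: Sequence[int],
    removal_alpha: float = 0.05,
) -> tuple[LogisticModel | None, list[str]]:
    """Backward stepwise logistic selection on Wald p-values.

    Starting from the full candidate model, repeatedly remove the
    variable with the largest Wald p >= ``removal_alpha`` and refit,
    until every retained variable is significant. Returns the final
    model (None when every candidate is removed) and the removal order.
    """
    X = pd.DataFrame(X)
    if X.shape[1] == 0:
        return None, []
    removed: list[str] = []
    current = list(X.columns)
    model = None
    while current:
        model = fit_logistic(X[current], y)
        worst = max(current, key=lambda v: model.p_values[v])
        if model.p_values[worst] >= removal_alpha:
            current.remove(worst)
            removed.append(worst)
            model = None
        else:
            break
    return model, removed


def loocv_metrics(
    X: pd.DataFrame,
    y: Sequence[int],
    cutoff: float = 0.5,
) -> CvMetrics:
    """Leave-one-out cross-validated sensitivity/specificity/accuracy.

    Each subject is predicted by a model fit on the other n - 1; the
    call is positive when the held-out probability >= ``cutoff``. Folds
    whose training outcome is single-class are skipped and counted.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 8:
        raise InsufficientDataError("LOOCV requires n >= 8")
    if len(set(y.tolist())) < 2:
        raise InsufficientDataError("outcome must contain both classes")
    rows = []
    n_skipped = 0
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if len(set(y[train].tolist())) < 2:
            n_skipped += 1
            continue
        model = fit_logistic(X.iloc[train], y[train])
        prob = float(model.predict(X.iloc[[i]])[0])
        rows.append((X.index[i], y[i], prob, int(prob >= cutoff)))
    pred = pd.DataFrame(rows, columns=["subject", "label", "probability", "call"])
    tp = int(((pred["label"] == 1) & (pred["call"] == 1)).sum())
    tn = int(((pred["label"] == 0) & (pred["call"] == 0)).sum())
    fp = int(((pred["label"] == 0) & (pred["call"] == 1)).sum())
    fn = int(((pred["label"] == 1) & (pred["call"] == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(pred) if len(pred) else 0.0
    return CvMetrics(sensitivity=sens, specificity=spec, accuracy=acc,
                     predictions=pred, n_skipped=n_skipped)


def model_roc(model: LogisticModel, X: pd.DataFrame, y: Sequence[int]) -> RocResult:
    """ROC of a fitted model's probabilities on a dataset."""
    probs = model.predict(pd.DataFrame(X).astype(float))
    return roc(probs, np.asarray(y).astype(bool), orientation="greater")


# ---------------------------------------------------------------------------
# univariate screening table


def univariate_screen(
    X: pd.DataFrame,
    y: Sequence[int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate logistic regression of the outcome on each column.

    Returns one row per variable with OR (95% CI), Wald p, and a
    candidate flag (p < ``alpha``) for the multivariate step.
    """
    rows = []
    for col in X.columns:
        m = fit_logistic(X[[col]], y)
        or_, lo, hi = m.odds_ratios[col]
        p = m.p_values[col]
        rows.append(
            {
                "variable": col,
                "odds_ratio": or_,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": p,
                "candidate": bool(p < alpha) and not m.separation,
                "separation": m.separation,
            }
        )
    return pd.DataFrame(rows)
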