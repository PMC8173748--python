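"""End-to-end analysis stages shared by the CLI and the test suite.

The cohort branch mirrors the clinical analysis: per-feature response
tables (group comparison + ROC), then dichotomization of the
mid-treatment imaging changes at their Youden cutpoints, univariate
logistic screening, backward stepwise multivariate modeling, model ROC
with a paired DeLong comparison against the single best imaging
predictor, and leave-one-out cross-validated classification metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import model as rm
from . import stats
from .features import feature_matrix
from .io import PipelineConfig
from .stats import RocResult


@dataclass
class PcrModelResult:
    """Everything the response-model stage produces."""

    univariate: pd.DataFrame
    final_model: rm.LogisticModel | None
    removed: list[str]
    summary: pd.DataFrame
    cv: rm.CvMetrics | None
    model_roc: RocResult | None
    reference_roc: RocResult | None
    delong_p: float | None
    thresholds: dict[str, float]
    roc_coordinates: pd.DataFrame


#: mid-treatment imaging changes entering the model, with the direction
#: (of the dichotomized positive category) that predicts response
IMAGING_CANDIDATES = {
    "delta_adc_200_1000": "above",
    "delta_size": "at_or_below",
    "delta_rer": "at_or_below",
}

CLINICAL_CANDIDATES = {
    # variable -> (covariate column, positive level meaning)
    "er_negative": ("er", 0),
    "pr_negative": ("pr", 0),
    "her2_positive": ("her2", 1),
    "ki67_high": ("ki67_class", 1),
}


def build_design(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Design matrix for the pCR model on mid-treatment-complete patients.

    Clinical covariates are coded with the response-enriched level as 1
    (ER negative, PR negative, HER2 positive, Ki-67 >= 20%); each
    continuous imaging change is dichotomized at its own Youden-optimal
    cutpoint estimated from the cohort ROC.
    """
    wide = feature_matrix(features, "mid", list(IMAGING_CANDIDATES))
    cov = covariates.set_index("patient_id")
    wide = wide.dropna()
    wide = wide.join(cov, how="inner")
    y = wide["pcr"].astype(int)

    X = pd.DataFrame(index=wide.index)
    for var, (col, positive_level) in CLINICAL_CANDIDATES.items():
        X[var] = (wide[col] == positive_level).astype(int)
    thresholds: dict[str, float] = {}
    for feat, direction in IMAGING_CANDIDATES.items():
        res = stats.roc(wide[feat].to_numpy(), y.to_numpy().astype(bool))
        thresholds[feat] = res.threshold
        X[f"{feat}_cat"] = rm.dichotomize(
            wide[feat].to_numpy(), res.threshold, direction
        )
    return X, y, thresholds


def roc_coordinates(values: Sequence[float], labels: Sequence[bool]) -> pd.DataFrame:
    """FPR/TPR pairs over all observed thresholds (for ROC curve export)."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = x[y], x[~y]
    rows = [(0.0, 0.0, np.inf)]
    for t in np.unique(x)[::-1]:
        rows.append((float(np.mean(neg >= t)), float(np.mean(pos >= t)), float(t)))
    return pd.DataFrame(rows, columns=["fpr", "tpr", "threshold"])


def pcr_model_pipeline(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PcrModelResult:
    """Univariate screening, stepwise model, LOOCV, and ROC comparison."""
    config = config or PipelineConfig()
    X, y, thresholds = build_design(features, covariates)

    uni = rm.univariate_screen(X, y, alpha=config.alpha)
    candidates = uni.loc[uni["candidate"], "variable"].tolist()
    final, removed = rm.backward_stepwise(
        X[candidates], y, removal_alpha=config.stepwise_alpha
    )

    rows = []
    for _, r in uni.iterrows():
        row = {
            "variable": r["variable"],
            "univariate_or": r["odds_ratio"],
            "univariate_ci_low": r["ci_low"],
            "univariate_ci_high": r["ci_high"],
            "univariate_p": r["p_value"],
            "multivariate_or": np.nan,
            "multivariate_ci_low": np.nan,
            "multivariate_ci_high": np.nan,
            "multivariate_p": np.nan,
        }
        if final is not None and r["variable"] in final.variables:
            or_, lo, hi = final.odds_ratios[r["variable"]]
            row.update(
                multivariate_or=or_,
                multivariate_ci_low=lo,
                multivariate_ci_high=hi,
                multivariate_p=final.p_values[r["variable"]],
            )
        rows.append(row)
    summary = pd.DataFrame(rows)

    cv = mroc = ref_roc = delong_p = None
    coords = pd.DataFrame(columns=["fpr", "tpr", "threshold"])
    if final is not None:
        cv = rm.loocv_metrics(X[list(final.variables)], y,
                              cutoff=config.loocv_cutoff)
        mroc = rm.model_roc(final, X, y)
        probs = final.predict(X)
        coords = roc_coordinates(probs, y.astype(bool))
        ref = "delta_adc_200_1000_cat"
        if ref in X.columns:
            ref_roc = stats.roc(X[ref].to_numpy(), y.to_numpy().astype(bool),
                                orientation="greater")
            delong_p = stats.delong_compare(
                probs, X[ref].to_numpy(dtype=float), y.to_numpy().astype(bool)
            )
    return PcrModelResult(
        univariate=uni,
        final_model=final,
        removed=removed,
        summary=summary,
        cv=cv,
        model_roc=mroc,
        reference_roc=ref_roc,
        delong_p=delong_p,
        thresholds=thresholds,
        roc_coordinates=coords,
    )
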