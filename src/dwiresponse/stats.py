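"""Group comparison and ROC machinery.

Implements the statistical engine behind the per-feature response
tables: Shapiro-Wilk normality screening routing to a t test or
Wilcoxon rank-sum test, chi-square / Fisher exact tests for 2x2 counts,
empirical ROC curves with DeLong variance and Youden-optimal cutpoints,
paired DeLong comparison of AUCs, and Bonferroni family control.

The empirical AUC is computed by the trapezoidal rule over all observed
thresholds, which is identical to Mann-Whitney pair counting with half
credit for ties; both routes are implemented (:func:`trapezoidal_auc`
and :func:`pair_counting_auc`) and must agree exactly on every input.
The DeLong (1988) variance comes from the sample covariance of the
placement values of positives and negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    PairingError,
    UndefinedRocError,
    UndefinedTableError,
    UnsupportedSampleError,
)

__all__ = [
    "RocResult",
    "ComparisonResult",
    "normality_screen",
    "compare_groups",
    "categorical_test",
    "roc",
    "delong_compare",
    "bonferroni_alpha",
    "trapezoidal_auc",
    "pair_counting_auc",
    "analyze_cohort",
]


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary for one predictor.

    ``orientation`` records which direction of the predictor indicates a
    positive outcome ("greater" or "less"); the Youden threshold is on
    the predictor's original scale, with the decision rule
    ``value > threshold`` (orientation "greater") or
    ``value < threshold`` (orientation "less").
    """

    auc: float
    variance: float
    ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    orientation: str
    p_value: float  # two-sided DeLong z test of AUC = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise UndefinedRocError("AUC outside [0, 1]")


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group or contingency test outcome."""

    test: str  # "t" | "wilcoxon" | "chi-square" | "fisher"
    statistic: float
    p_value: float


class BonferroniAlpha(NamedTuple):
    exact: float
    display: float


# ---------------------------------------------------------------------------
# group comparison


def normality_screen(values: Sequence[float]) -> float:
    """Shapiro-Wilk p-value for one sample (3 <= n <= 5000).

    A degenerate constant sample returns p = 0.0 (flagged non-normal).
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise UnsupportedSampleError(
            f"Shapiro-Wilk supported for 3 <= n <= 5000, got n={x.size}"
        )
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    force: str | None = None,
    alpha_normal: float = 0.05,
) -> ComparisonResult:
    """Two-group comparison with normality-routed test choice.

    Both samples are screened with Shapiro-Wilk; if both look normal
    (p >= ``alpha_normal``) an independent-samples t test is used,
    otherwise the Wilcoxon rank-sum (Mann-Whitney) test. ``force`` may
    be "t" or "wilcoxon" to bypass the screen. Two-sided p-values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least two values")
    if force is None:
        normal = (
            normality_screen(a) >= alpha_normal
            and normality_screen(b) >= alpha_normal
        )
        test = "t" if normal else "wilcoxon"
    elif force in ("t", "wilcoxon"):
        test = force
    else:
        raise ConfigurationError(f"unknown test {force!r}")
    if test == "t":
        res = sps.ttest_ind(a, b, equal_var=True)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return ComparisonResult(test=test, statistic=float(res.statistic),
                            p_value=float(res.pvalue))


def categorical_test(table: Sequence[Sequence[int]]) -> ComparisonResult:
    """Chi-square test of a 2x2 table, or Fisher exact when any expected
    count falls below 5. No continuity correction (large samples)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise UndefinedTableError("need a 2x2 table of non-negative integers")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise UndefinedTableError("table has an all-zero margin")
    expected = np.outer(rows, cols) / t.sum()
    if expected.min() < 5:
        odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
        return ComparisonResult(test="fisher", statistic=float(odds), p_value=float(p))
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return ComparisonResult(test="chi-square", statistic=float(chi2), p_value=float(p))


def bonferroni_alpha(alpha: float, m: int) -> BonferroniAlpha:
    """Bonferroni-adjusted per-comparison level alpha/m.

    ``exact`` is the unrounded value used for decisions; ``display`` is
    rounded to four decimals for table footnotes.
    """
    if m < 1:
        raise ConfigurationError("number of comparisons must be >= 1")
    exact = alpha / m
    return BonferroniAlpha(exact=exact, display=round(exact, 4))


# ---------------------------------------------------------------------------
# ROC


def _split(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels).astype(bool)
    x = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise PairingError("values and labels differ in length")
    pos, neg = x[y], x[~y]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedRocError("ROC requires both outcome classes")
    return pos, neg


def trapezoidal_auc(values: Sequence[float], labels: Sequence[bool]) -> float:
    """Empirical AUC by the trapezoidal rule over all observed thresholds
    (greater value predicts a positive label)."""
    pos, neg = _split(np.asarray(values, float), np.asarray(labels))
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(np.mean(pos >= t))
        fpr.append(np.mean(neg >= t))
    return float(np.trapezoid(tpr, fpr))


def pair_counting_auc(values: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) pairs ranked
    concordantly, with half credit for ties. Rank-based, O(n log n)."""
    pos, neg = _split(np.asarray(values, float), np.asarray(labels))
    combined = np.concatenate([pos, neg])
    ranks = sps.rankdata(combined)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    v10, v01 = _placements(pos, neg)
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    return float(s10 / pos.size + s01 / neg.size)


def roc(
    values: Sequence[float],
    labels: Sequence[bool],
    orientation: str = "auto",
) -> RocResult:
    """Empirical ROC with DeLong CI and Youden-optimal threshold.

    ``orientation='auto'`` fixes the predictor's direction from the sign
    of the group-mean difference so AUC >= 0.5 by construction. The
    Youden threshold maximizes J = sensitivity + specificity - 1 over
    observed values; ties resolve to the larger sensitivity, then the
    smaller threshold. The p-value is a two-sided DeLong z test of
    AUC = 0.5; the 95% CI is normal-approximation, clipped to [0, 1].
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = _split(x, y)
    if orientation == "auto":
        orientation = "greater" if pos.mean() >= neg.mean() else "less"
    if orientation not in ("greater", "less"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    s = x if orientation == "greater" else -x
    spos, sneg = (pos, neg) if orientation == "greater" else (-pos, -neg)

    auc = trapezoidal_auc(s, y)
    var = _delong_variance(spos, sneg)
    half = 1.959963984540054 * math.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    if var > 0:
        z = (auc - 0.5) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        p = 1.0 if auc == 0.5 else 0.0

    # Youden scan over observed (oriented) thresholds; rule is "> t".
    candidates = np.concatenate([[-np.inf], np.unique(s)])
    best = None
    for t in candidates:
        sens = float(np.mean(spos > t))
        spec = float(np.mean(sneg <= t))
        j = sens + spec - 1.0
        key = (round(j, 12), round(sens, 12), -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t_star, sens, spec = best
    threshold = float(t_star if orientation == "greater" else -t_star)
    return RocResult(
        auc=float(auc), variance=var, ci=ci, threshold=threshold,
        sensitivity=sens, specificity=spec, orientation=orientation,
        p_value=float(p),
    )


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> float:
    """Two-sided DeLong p-value for the difference of two paired AUCs."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if a.shape != b.shape or a.shape != y.shape:
        raise PairingError("paired scores and labels must have equal length")
    pos_a, neg_a = _split(a, y)
    pos_b, neg_b = _split(b, y)
    v10 = np.column_stack(
        [_placements(pos_a, neg_a)[0], _placements(pos_b, neg_b)[0]]
    )
    v01 = np.column_stack(
        [_placements(pos_a, neg_a)[1], _placements(pos_b, neg_b)[1]]
    )
    auc_a, auc_b = v10[:, 0].mean(), v10[:, 1].mean()
    m, n = v10.shape[0], v01.shape[0]
    s10 = np.cov(v10, rowvar=False) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, rowvar=False) if n > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# cohort analysis (per-feature response tables)


#: Bonferroni family sizes: 7 DWI variables x 3 timepoints, 2 CE x 3.
FAMILY_SIZES = {"dwi": 21, "ce": 6}

_DWI = ("adc_0_1000", "adc_200_1000", "adc_all", "d_star", "f", "ddc", "alpha")
_CE = ("size", "rer")


def analyze_cohort(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature, per-timepoint group comparison and ROC table.

    For every feature, the pre-treatment value and the mid/post changes
    from baseline are compared between pCR and non-pCR groups, with the
    group test chosen by normality screening, the empirical AUC with
    DeLong 95% CI and p-value, and a Bonferroni-adjusted significance
    flag (family size 21 for DWI variables, 6 for CE variables).

    ``features`` is the tidy table from
    :func:`dwiresponse.features.assemble_features`; ``covariates`` must
    carry ``patient_id`` and ``pcr``.
    """
    labels = covariates.set_index("patient_id")["pcr"].astype(bool)
    rows = []
    for family, names in (("dwi", _DWI), ("ce", _CE)):
        adj = bonferroni_alpha(alpha, FAMILY_SIZES[family])
        for name in names:
            for tp in ("pre", "mid", "post"):
                feat = name if tp == "pre" else f"delta_{name}"
                sub = features[
                    (features["timepoint"] == tp) & (features["feature"] == feat)
                ]
                if sub.empty:
                    continue
                vals = sub.set_index("patient_id")["value"]
                y = labels.loc[vals.index].to_numpy()
                a = vals.to_numpy()[y]
                b = vals.to_numpy()[~y]
                comp = compare_groups(a, b)
                roc_res = roc(vals.to_numpy(), y)
                rows.append(
                    {
                        "feature": feat,
                        "timepoint": tp,
                        "family": family,
                        "n_pcr": int(y.sum()),
                        "n_non_pcr": int((~y).sum()),
                        "mean_pcr": float(a.mean()),
                        "sd_pcr": float(a.std(ddof=1)),
                        "mean_non_pcr": float(b.mean()),
                        "sd_non_pcr": float(b.std(ddof=1)),
                        "test": comp.test,
                        "p_value": comp.p_value,
                        "auc": roc_res.auc,
                        "auc_ci_low": roc_res.ci[0],
                        "auc_ci_high": roc_res.ci[1],
                        "auc_p_value": roc_res.p_value,
                        "youden_threshold": roc_res.threshold,
                        "orientation": roc_res.orientation,
                        "adjusted_alpha": adj.exact,
                        "significant": comp.p_value < adj.exact,
                    }
                )
    return pd.DataFrame(rows)
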