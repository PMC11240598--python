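"""Diagnostic statistics: logistic association, ROC, and AUC comparison.

The diagnostic endpoint is binary: cancer or atypical hyperplasia
(histology AEH, EM G1-G3, or serous/clear-cell "Others") versus benign
(Normal or EH).  Candidate markers are the specimen-level morphometric
descriptors.  The module provides

* odds ratios per descriptor, unadjusted and adjusted for menopausal
  age (>= 55 years) and the dichotomized cytology result;
* empirical ROC curves with the Mann-Whitney AUC, DeLong confidence
  intervals, and the Youden-index cutoff;
* the paired DeLong test for comparing the cytology-alone AUC with the
  AUC of cytology combined with a descriptor (in-sample logistic
  combination);
* the binormal variance-function sample-size computation for detecting
  an AUC above 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "POSITIVE_CLASSES",
    "NEGATIVE_CLASSES",
    "dichotomize",
    "LogisticResult",
    "fit_logistic",
    "RocResult",
    "roc_curve",
    "delong_variance",
    "combined_score",
    "delong_paired_test",
    "auc_sample_size",
]

POSITIVE_CLASSES = frozenset({"AEH", "EM_G1", "EM_G2", "EM_G3", "Others"})
NEGATIVE_CLASSES = frozenset({"Normal", "EH"})


def dichotomize(
    histology: str, age: float, cytology: str
) -> tuple[bool, bool, bool]:
    """Map a patient record to (positive_class, age55, cytology_flag).

    Positive class is AEH or cancer; age is split at >= 55 years
    (inclusive boundary); the three-tier cytology collapses to
    positive-or-suspicious versus negative.
    """
    if histology in POSITIVE_CLASSES:
        label = True
    elif histology in NEGATIVE_CLASSES:
        label = False
    else:
        raise ValueError(f"unknown histology class {histology!r}")
    if cytology not in ("negative", "suspicious_positive", "positive"):
        raise ValueError(f"unknown cytology category {cytology!r}")
    return label, age >= 55.0, cytology != "negative"


@dataclass
class LogisticResult:
    """Odds ratios from a maximum-likelihood logistic fit."""

    odds_ratio: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_value: dict[str, float]
    coef: dict[str, float]
    adjusted: bool
    covariates: list[str]
    separation: bool = False
    fitted_prob: np.ndarray | None = None


def fit_logistic(
    outcome: np.ndarray,
    predictors: pd.DataFrame | np.ndarray,
    names: list[str] | None = None,
) -> LogisticResult:
    """Logistic regression with Wald CIs on the exponentiated scale.

    ``predictors`` holds one column per term (the first is convention-
    ally the marker of interest, the rest adjusters).  Complete or
    quasi-complete separation is detected and flagged rather than
    silently returning a diverged fit.
    """
    y = np.asarray(outcome, float)
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(float)
    else:
        X = np.atleast_2d(np.asarray(predictors, float))
        if X.shape[0] == 1 and y.size > 1:
            X = X.T
        if names is None:
            names = [f"x{i + 1}" for i in range(X.shape[1])]
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one event and one non-event")
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    fitted = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = np.asarray(fit.params)[1:]
            bse = np.asarray(fit.bse)[1:]
            fitted = np.asarray(fit.predict(Xc))
        except (np.linalg.LinAlgError,
                sm.tools.sm_exceptions.PerfectSeparationError):
            # (quasi-)complete separation: report the direction of the
            # diverging estimate via a lightly ridge-penalized fit, with
            # infinite standard errors
            separation = True
            glm = sm.GLM(y, Xc, family=sm.families.Binomial())
            res = glm.fit_regularized(alpha=1e-6, L1_wt=0.0)
            params = np.asarray(res.params)[1:]
            bse = np.full(params.size, np.inf)
            fitted = np.asarray(glm.predict(res.params, Xc))
    if np.any(~np.isfinite(bse)) or np.any(np.abs(params) > 30):
        separation = True
    z = norm.ppf(0.975)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        or_ = np.exp(params)
        lo = np.exp(params - z * bse)
        hi = np.exp(params + z * bse)
        pvals = 2.0 * norm.sf(np.abs(params / bse))
    return LogisticResult(
        odds_ratio=dict(zip(names, or_)),
        ci_low=dict(zip(names, lo)),
        ci_high=dict(zip(names, hi)),
        p_value=dict(zip(names, pvals)),
        coef=dict(zip(names, params)),
        adjusted=len(names) > 1,
        covariates=names,
        separation=separation,
        fitted_prob=fitted,
    )


@dataclass
class RocResult:
    """Empirical ROC curve with Mann-Whitney AUC and Youden cutoff."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    ci_low: float
    ci_high: float
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    n_positive: int
    n_negative: int


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values and the tie-corrected AUC."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    # P(pos > neg) + 0.5 P(=) via pairwise comparison in vectorized form
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)          # one per positive
    v01 = psi.mean(axis=0)          # one per negative
    return v10, v01, float(psi.mean())


def delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """(AUC, variance) of the empirical AUC by DeLong's estimator."""
    v10, v01, auc = _placements(pos, neg)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_curve(score: np.ndarray, label: np.ndarray) -> RocResult:
    """Empirical ROC of a positively oriented continuous score.

    The AUC is the Mann-Whitney statistic (ties counted 1/2) with a
    DeLong standard error; the reported cutoff maximizes the Youden
    index J = sensitivity + specificity - 1, ties broken toward higher
    specificity.  Thresholds are midpoints between consecutive distinct
    scores (score >= threshold calls positive).
    """
    score = np.asarray(score, float)
    label = np.asarray(label, bool)
    pos, neg = score[label], score[~label]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(score)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    auc, var = delong_variance(pos, neg)
    se = math.sqrt(var)
    j = sens + spec - 1.0
    # lexicographic: maximize J, then specificity
    best = np.lexsort((spec, j))[-1]
    z = norm.ppf(0.975)
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=auc, auc_se=se,
        ci_low=max(0.0, auc - z * se), ci_high=min(1.0, auc + z * se),
        cutoff=float(thresholds[best]),
        sens_at_cutoff=float(sens[best]), spec_at_cutoff=float(spec[best]),
        n_positive=pos.size, n_negative=neg.size)


def combined_score(
    cytology_flag: np.ndarray,
    feature: np.ndarray,
    label: np.ndarray,
) -> tuple[np.ndarray, LogisticResult]:
    """In-sample logistic combination of cytology and one descriptor.

    Returns the fitted probability for each patient (a score whose ROC
    can be compared with cytology alone) together with the fit.  The
    model is fitted and evaluated on the same cohort — apparent, not
    cross-validated, performance.
    """
    X = pd.DataFrame({
        "cytology": np.asarray(cytology_flag, float),
        "feature": np.asarray(feature, float),
    })
    fit = fit_logistic(np.asarray(label, float), X)
    return fit.fitted_prob, fit


def delong_paired_test(
    score_a: np.ndarray,
    score_b: np.ndarray,
    label: np.ndarray,
) -> tuple[float, float, float]:
    """DeLong test for two correlated AUCs on the same patients.

    Returns (auc_a, auc_b, two-sided p).  The covariance of the paired
    AUC estimates comes from the placement values; a degenerate
    variance (e.g. identical scores) yields p = 1.
    """
    label = np.asarray(label, bool)
    a_pos, a_neg = np.asarray(score_a, float)[label], np.asarray(score_a, float)[~label]
    b_pos, b_neg = np.asarray(score_b, float)[label], np.asarray(score_b, float)[~label]
    if a_pos.size == 0 or a_neg.size == 0:
        raise ValueError("both classes must be present")
    va10, va01, auc_a = _placements(a_pos, a_neg)
    vb10, vb01, auc_b = _placements(b_pos, b_neg)
    m, n = va10.size, va01.size
    if m > 1 and n > 1:
        s10 = np.cov(np.vstack([va10, vb10]))
        s01 = np.cov(np.vstack([va01, vb01]))
        cov = s10 / m + s01 / n
    else:
        cov = np.zeros((2, 2))
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 1e-16:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    return auc_a, auc_b, float(2.0 * norm.sf(abs(z)))


def auc_sample_size(
    auc_alt: float,
    alpha: float = 0.05,
    power: float = 0.90,
    ratio: float = 1.0,
) -> int:
    """Cases per group to distinguish an AUC from 0.5.

    Binormal variance-function method: with a = sqrt(2) * Phi^-1(theta)
    and V(theta) = 0.0099 * exp(-a^2/2) * (6 a^2 + 16),

        n = (z_{1-alpha/2} sqrt(V(0.5)) + z_power sqrt(V(theta)))^2
            / (theta - 0.5)^2,

    rounded to the nearest integer.  ``ratio`` is the size of the
    second group relative to the first (1 means equal groups).
    """
    if not 0.5 < auc_alt < 1.0:
        raise ValueError("auc_alt must be in (0.5, 1)")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")

    def v(theta: float) -> float:
        a = math.sqrt(2.0) * norm.ppf(theta)
        return 0.0099 * math.exp(-a * a / 2.0) * (6.0 * a * a + 16.0)

    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_b = norm.ppf(power)
    n = (z_a * math.sqrt(v(0.5)) + z_b * math.sqrt(v(auc_alt))) ** 2 \
        / (auc_alt - 0.5) ** 2
    return int(round(n * max(1.0, 1.0 / ratio)))
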