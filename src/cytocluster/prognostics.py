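"""Survival machinery: Kaplan-Meier, log-rank, outcome-based cutpoints, Cox.

A continuous morphometric marker is turned into a prognostic factor by
scanning candidate cutoffs and keeping the split that maximizes the
two-group log-rank statistic (the maximally-selected log-rank cutpoint
familiar from clinical cutoff software).  Because the maximum over a
scan is anti-conservative, the
scan also offers a permutation-corrected p-value: the marker vector is
permuted against the (time, event) pairs and the maximal chi-square is
recomputed, giving the null distribution of the scan maximum itself.

Hazard ratios come from Cox proportional-hazards fits (Efron or
Breslow ties), univariable or adjusted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2 as chi2_dist
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "km_estimate",
    "logrank_test",
    "two_group_logrank_chi2",
    "cutpoint_scan_chi2",
    "CutpointResult",
    "optimal_cutpoint",
    "CoxFit",
    "cox_fit",
    "SUBSET_PRESETS",
]

# Histology subsets used in the prognostic analyses: all cancers,
# endometrioid only, and high-grade endometrioid.
SUBSET_PRESETS = {
    "all_ec": ("EM_G1", "EM_G2", "EM_G3", "Others"),
    "em_g1_g3": ("EM_G1", "EM_G2", "EM_G3"),
    "em_g2_g3": ("EM_G2", "EM_G3"),
}


def km_estimate(
    times: np.ndarray,
    events: np.ndarray,
    group: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group with Greenwood variance.

    Returns, per group label, a step table with columns ``survival``,
    ``variance`` (Greenwood), ``ci_low`` and ``ci_high`` indexed by
    time.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.size == 0:
        raise ValueError("empty group")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if group is None:
        group = np.zeros(times.size, int)
    group = np.asarray(group)
    out: dict[str, pd.DataFrame] = {}
    for g in np.unique(group):
        sel = group == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        surv = kmf.survival_function_.iloc[:, 0]
        ci = kmf.confidence_interval_
        # Greenwood variance from the reported SE-free tables:
        # lifelines exposes it via the cumulative hazard machinery; we
        # recompute it directly from the risk table for transparency.
        tab = kmf.event_table
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = tab["observed"] / (
                tab["at_risk"] * (tab["at_risk"] - tab["observed"]))
        terms = terms.replace([np.inf, -np.inf], np.nan).fillna(0.0)
        var = surv.values**2 * np.cumsum(terms.values)
        out[str(g)] = pd.DataFrame({
            "survival": surv.values,
            "variance": var,
            "ci_low": ci.iloc[:, 0].values,
            "ci_high": ci.iloc[:, 1].values,
        }, index=surv.index.rename("time"))
    return out


def logrank_test(
    times: np.ndarray,
    events: np.ndarray,
    group: np.ndarray,
) -> tuple[float, float]:
    """k-group log-rank test; returns (chi_square, p) with k-1 df."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group)
    labels, counts = np.unique(group, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    if np.any(counts == 0):
        raise ValueError("each group needs at least one subject")
    res = multivariate_logrank_test(times, group, events)
    return float(res.test_statistic), float(res.p_value)


def two_group_logrank_chi2(
    times: np.ndarray, events: np.ndarray, in_group1: np.ndarray
) -> float:
    """Two-group log-rank chi-square, vectorized (used by the scan)."""
    chi = cutpoint_scan_chi2(times, events,
                             np.asarray(in_group1, bool)[None, :])
    return float(chi[0])


def cutpoint_scan_chi2(
    times: np.ndarray,
    events: np.ndarray,
    group1_matrix: np.ndarray,
) -> np.ndarray:
    """Log-rank chi-square for many candidate dichotomies at once.

    ``group1_matrix`` is (n_candidates, n_subjects) boolean; row k
    defines membership of group 1 under candidate split k.  Returns the
    chi-square of each split (NaN where a split is degenerate, i.e.
    one group empty or no variance).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    G = np.asarray(group1_matrix, bool)
    order = np.argsort(times, kind="stable")
    t = times[order]
    d = events[order].astype(float)
    G = G[:, order]
    n = t.size
    # group boundaries of tied event times
    uniq, start = np.unique(t, return_index=True)
    # at-risk counts just before each time index: suffix sums
    at_risk_total = n - np.arange(n)                 # at index i: n - i
    n1_suffix = np.cumsum(G[:, ::-1].astype(np.int64), axis=1)[:, ::-1]
    # events per unique time, and group-1 events per unique time
    d_tot = np.add.reduceat(d, start)
    d1 = np.add.reduceat(G * d[None, :], start, axis=1)
    n_tot = at_risk_total[start].astype(float)
    n1 = n1_suffix[:, start].astype(float)
    has_event = d_tot > 0
    dt = d_tot[has_event]
    nt = n_tot[has_event]
    n1e = n1[:, has_event]
    d1e = d1[:, has_event]
    frac = n1e / nt
    O = d1e.sum(axis=1)
    E = (dt * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        hyper = dt * frac * (1.0 - frac) * np.where(nt > 1, (nt - dt) / (nt - 1.0), 0.0)
    V = hyper.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = (O - E) ** 2 / V
    chi[V <= 0] = np.nan
    return chi


@dataclass
class CutpointResult:
    """Outcome of the outcome-based cutpoint scan for one marker."""

    feature: str
    candidates: np.ndarray
    chi_squares: np.ndarray
    cutoff: float
    chi_square: float
    p_uncorrected: float
    p_corrected: float | None
    n_low: int
    n_high: int
    orientation: str          # which side is the risk group


def optimal_cutpoint(
    feature: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    min_group_frac: float = 0.10,
    orientation: str = "low_risk_below",
    feature_name: str = "feature",
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> CutpointResult:
    """Choose the marker cutoff maximizing the log-rank separation.

    Candidates are midpoints between consecutive distinct marker
    values whose split leaves at least ``min_group_frac`` of subjects
    on each side.  The reported ``p_uncorrected`` refers the maximal
    chi-square to its nominal 1-df distribution and is anti-conservative
    by construction; with ``n_permutations`` > 0 a permutation-corrected
    p-value for the scan maximum is added.

    ``orientation`` records which side is treated as the risk group
    ("low_risk_below" marks values below the cutoff as the risk group,
    as for circularity/solidity; "high_risk_above" likewise for markers
    such as the fractal dimension) — it does not affect the statistic,
    only downstream labeling.
    """
    feature = np.asarray(feature, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    n = feature.size
    if not events.any():
        raise ValueError("no events")
    uniq = np.unique(feature)
    if uniq.size < 2:
        raise ValueError("feature is constant; no admissible cutoff")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    min_n = max(1, int(math.ceil(min_group_frac * n)))
    below = (feature[None, :] <= mids[:, None])
    sizes = below.sum(axis=1)
    ok = (sizes >= min_n) & (n - sizes >= min_n)
    if not ok.any():
        raise ValueError("no admissible cutoff under the group-size constraint")
    mids = mids[ok]
    below = below[ok]
    chi = cutpoint_scan_chi2(times, events, below)
    chi_clean = np.where(np.isnan(chi), -np.inf, chi)
    best = int(np.argmax(chi_clean))
    best_chi = float(chi_clean[best])
    if not np.isfinite(best_chi):
        raise ValueError("all candidate splits degenerate")
    p_unc = float(chi2_dist.sf(best_chi, 1))
    p_corr = None
    if n_permutations > 0:
        if rng is None:
            rng = np.random.default_rng()
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            chi_p = cutpoint_scan_chi2(times, events, below[:, perm])
            m = np.nanmax(chi_p) if not np.all(np.isnan(chi_p)) else -np.inf
            if m >= best_chi:
                exceed += 1
        p_corr = (exceed + 1.0) / (n_permutations + 1.0)
    n_low = int(below[best].sum())
    return CutpointResult(
        feature=feature_name, candidates=mids, chi_squares=chi,
        cutoff=float(mids[best]), chi_square=best_chi,
        p_uncorrected=p_unc, p_corrected=p_corr,
        n_low=n_low, n_high=n - n_low, orientation=orientation)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    hazard_ratio: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_value: dict[str, float]
    coef: dict[str, float]
    ties: str
    covariates: list[str]
    n_events: int
    monotone_likelihood: bool = False


def cox_fit(
    covariates: pd.DataFrame | np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str = "efron",
    names: list[str] | None = None,
) -> CoxFit:
    """Cox partial-likelihood fit with Wald CIs.

    ``ties`` selects the Efron (default) or Breslow approximation.
    A singular design (duplicated or collinear covariates) raises; a
    covariate that perfectly orders the events (monotone likelihood)
    is flagged on the returned fit.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(float)
    else:
        X = np.atleast_2d(np.asarray(covariates, float))
        if X.shape[0] == 1 and np.asarray(times).size > 1:
            X = X.T
        if names is None:
            names = [f"x{i + 1}" for i in range(X.shape[1])]
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    n_events = int(events.sum())
    if n_events < X.shape[1]:
        warnings.warn("fewer events than covariates; estimates unstable",
                      stacklevel=2)
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < X.shape[1]:
        raise ValueError("singular design: collinear covariates")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PHReg(times, X, status=events.astype(int), ties=ties)
        fit = model.fit(maxiter=200)
    params = np.asarray(fit.params)
    bse = np.asarray(fit.bse)
    monotone = bool(np.any(np.abs(params) > 20) or np.any(~np.isfinite(bse)))
    from scipy.stats import norm
    z = norm.ppf(0.975)
    with np.errstate(over="ignore", invalid="ignore"):
        hr = np.exp(params)
        lo = np.exp(params - z * bse)
        hi = np.exp(params + z * bse)
        p = 2.0 * norm.sf(np.abs(params / bse))
    return CoxFit(
        hazard_ratio=dict(zip(names, hr)),
        ci_low=dict(zip(names, lo)), ci_high=dict(zip(names, hi)),
        p_value=dict(zip(names, p)), coef=dict(zip(names, params)),
        ties=ties, covariates=names, n_events=n_events,
        monotone_likelihood=monotone)
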