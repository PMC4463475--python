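"""Serial CA-125 risk model: change-point likelihood ratio and triage bands.

The risk calculation compares two generative models for a woman's serial
log CA-125 profile.  Under the healthy model the log marker is flat,

    y_ij = theta_i + eps_ij,      theta_i ~ N(mu0, tau2),  eps_ij ~ N(0, sigma2),

where ``theta_i`` is the woman's stable baseline (between-woman variance
``tau2``) and ``eps_ij`` is within-woman assay plus biological noise.  Under
the case model the log marker rises linearly after a latent change point
``tau`` at slope ``gamma`` (per year),

    y_ij = theta_i + gamma * max(0, t_ij - tau) + eps_ij,

and the marginal likelihood mixes over a grid of (change point, slope)
cells with prior weights.  In both models ``theta_i`` is integrated out
analytically, which leaves a multivariate normal with compound-symmetry
covariance ``sigma2 * I + tau2 * J``.

The posterior probability of undiagnosed cancer given a prior ``p`` per
annual screen is

    risk = p * L_case / (p * L_case + (1 - p) * L_healthy),

computed in log space, and is mapped onto the trial's triage bands
(normal / intermediate / elevated / severe) by fixed risk cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy.special import expit, logit, logsumexp

_LOG_2PI = math.log(2.0 * math.pi)

#: Prior probability of undiagnosed ovarian cancer per annual screen.
#: Roughly one case per 2,000 woman-years in postmenopausal women age >= 50.
DEFAULT_PRIOR = 1.0 / 2000.0


class Triage(str, Enum):
    """Risk bands governing repeat testing, imaging and surgical referral."""

    NORMAL = "Normal"
    INTERMEDIATE = "Intermediate"
    ELEVATED = "Elevated"
    SEVERE = "Severe"


@dataclass(frozen=True, eq=False)
class BiomarkerSeries:
    """One woman's time-ordered CA-125 measurements.

    Parameters
    ----------
    subject_id
        Opaque identifier.
    times
        Sample times in years since cohort entry, strictly increasing.
    values
        CA-125 concentrations in U/mL, strictly positive.
    age_at_entry
        Age in years at cohort entry.
    """

    subject_id: str
    times: np.ndarray
    values: np.ndarray
    age_at_entry: float = 60.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size or t.size < 1:
            raise ValueError(
                "times and values must be one-dimensional, equal length and non-empty"
            )
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"sample times must be strictly increasing (subject {self.subject_id!r})"
            )
        if not (np.all(np.isfinite(v)) and np.all(v > 0)):
            raise ValueError(
                f"CA-125 values must be positive and finite (subject {self.subject_id!r})"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def log_values(self) -> np.ndarray:
        return np.log(self.values)

    def extended(self, time: float, value: float) -> "BiomarkerSeries":
        """Return a new series with one additional (later) sample appended."""
        return BiomarkerSeries(
            self.subject_id,
            np.append(self.times, float(time)),
            np.append(self.values, float(value)),
            self.age_at_entry,
        )


@dataclass(frozen=True)
class HealthyModelParams:
    """Hyperparameters of the flat (healthy) log CA-125 model.

    Defaults: ``mu0 = log(14)`` gives a control median of 14 U/mL;
    ``tau2 = 0.18`` (between-woman log variance) plus ``sigma2 = 0.0225``
    (within-woman variance, a ~15% serial coefficient of variation —
    serial CA-125 is very stable within a healthy postmenopausal woman,
    which is the premise of longitudinal interpretation) give a total
    control log-SD of 0.45, under which about 2% of control screens exceed
    the conventional 35 U/mL cutoff.  These are configuration, not
    estimates from any dataset.
    """

    mu0: float = math.log(14.0)
    tau2: float = 0.18
    sigma2: float = 0.0225

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass(frozen=True, eq=False)
class CaseModelParams:
    """Grid mixture defining the change-point (case) model.

    The change-point grid is expressed in years on the same clock as the
    sample times; cells with a change point beyond the last sample time
    reduce exactly to the healthy model.  Slopes are per-year rises of the
    log marker and must be positive.  Each weight vector sums to one.
    """

    healthy_component: HealthyModelParams
    changepoint_grid: np.ndarray
    slope_grid: np.ndarray
    changepoint_weights: np.ndarray
    slope_weights: np.ndarray

    def __post_init__(self) -> None:
        cp = np.asarray(self.changepoint_grid, dtype=float)
        sl = np.asarray(self.slope_grid, dtype=float)
        cw = np.asarray(self.changepoint_weights, dtype=float)
        sw = np.asarray(self.slope_weights, dtype=float)
        if cp.size == 0 or sl.size == 0:
            raise ValueError("change-point and slope grids must be non-empty")
        if not np.all(sl > 0):
            raise ValueError("all slopes must be positive")
        if cw.size != cp.size or sw.size != sl.size:
            raise ValueError("weight vectors must match their grids in length")
        if np.any(cw < 0) or np.any(sw < 0):
            raise ValueError("weights must be non-negative")
        for w, name in ((cw, "changepoint_weights"), (sw, "slope_weights")):
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {w.sum()!r})")
        object.__setattr__(self, "changepoint_grid", cp)
        object.__setattr__(self, "slope_grid", sl)
        object.__setattr__(self, "changepoint_weights", cw)
        object.__setattr__(self, "slope_weights", sw)


@dataclass(frozen=True)
class TriageThresholds:
    """Risk cutoffs for the four triage bands.

    Defaults are the post-April-2005 cutoffs (intermediate 1/3,500,
    elevated 1/1,000); :meth:`for_era` selects the original pre-2005
    values (1/1,818 and 1/500).  The severe cutoff of 1/5 triggers a
    surgery recommendation irrespective of scan findings.
    """

    intermediate_cut: float = 1.0 / 3500.0
    elevated_cut: float = 1.0 / 1000.0
    severe_cut: float = 1.0 / 5.0
    era: str = "post2005"

    def __post_init__(self) -> None:
        if not (0.0 < self.intermediate_cut < self.elevated_cut < self.severe_cut < 1.0):
            raise ValueError("require 0 < intermediate < elevated < severe < 1")

    @classmethod
    def for_era(cls, era: str) -> "TriageThresholds":
        if era == "post2005":
            return cls()
        if era == "pre2005":
            return cls(1.0 / 1818.0, 1.0 / 500.0, 1.0 / 5.0, era="pre2005")
        raise ValueError(f"unknown era {era!r}; expected 'pre2005' or 'post2005'")


@dataclass(frozen=True)
class RiskResult:
    """Posterior risk for one screen together with its triage band."""

    risk: float
    log_lik_healthy: float
    log_lik_case: float
    triage: Triage


def _cs_logpdf(resid: np.ndarray, tau2: float, sigma2: float) -> np.ndarray:
    """Log density of residuals under N(0, sigma2*I + tau2*J).

    This is the flat hierarchical model with the subject baseline
    integrated out.  ``resid`` may carry leading batch axes; the last axis
    indexes samples.  Uses the closed-form determinant and inverse of the
    compound-symmetry covariance, so no matrix factorisation is needed.
    """
    n = resid.shape[-1]
    s = resid.sum(axis=-1)
    q = np.square(resid).sum(axis=-1)
    denom = sigma2 + n * tau2
    quad = (q - tau2 * s * s / denom) / sigma2
    logdet = n * math.log(sigma2) + math.log(denom / sigma2)
    return -0.5 * (n * _LOG_2PI + logdet + quad)


def log_marginal_flat(series: BiomarkerSeries, params: HealthyModelParams) -> float:
    """Log marginal likelihood of the series under the flat (healthy) model."""
    resid = series.log_values - params.mu0
    return float(_cs_logpdf(resid, params.tau2, params.sigma2))


def log_marginal_changepoint(series: BiomarkerSeries, params: CaseModelParams) -> float:
    """Log marginal likelihood under the change-point mixture (case) model.

    Each (slope, change point) cell shifts the mean by
    ``slope * max(0, t - changepoint)``; the subject baseline is integrated
    analytically per cell and cells are combined by log-sum-exp with the
    prior weights.  Cells with zero weight are ignored exactly.
    """
    h = params.healthy_component
    t = series.times
    z = series.log_values - h.mu0
    # (n_slopes, n_changepoints, n_samples) mean shift
    shift = params.slope_grid[:, None, None] * np.maximum(
        0.0, t[None, None, :] - params.changepoint_grid[None, :, None]
    )
    cell_ll = _cs_logpdf(z[None, None, :] - shift, h.tau2, h.sigma2)
    with np.errstate(divide="ignore"):
        logw = np.log(params.slope_weights)[:, None] + np.log(params.changepoint_weights)[None, :]
    return float(logsumexp(cell_ll + logw))


@lru_cache(maxsize=1024)
def default_case_params(
    window_end: float,
    healthy: HealthyModelParams | None = None,
    lookback_years: float = 5.0,
    n_slopes: int = 8,
    doubling_time_months: tuple[float, float] = (1.5, 18.0),
) -> CaseModelParams:
    """Default change-point grid for a series ending at ``window_end`` years.

    The change point runs on a monthly grid over the ``lookback_years``
    preceding the last sample, plus one cell beyond the observation window
    (which reduces to the healthy model, so the mixture never assigns zero
    likelihood to a healthy-looking profile).  Slopes are log-spaced over
    log CA-125 doubling times of 1.5 to 18 months, bracketing the rapid
    doubling reported for ovarian tumours.  Weights are uniform.
    """
    healthy = healthy if healthy is not None else HealthyModelParams()
    n_cp = int(round(lookback_years * 12.0)) + 1
    cps = window_end - np.arange(n_cp - 1, -1, -1) / 12.0
    cps = np.append(cps, window_end + 1.0)
    dts_years = np.geomspace(doubling_time_months[0], doubling_time_months[1], n_slopes) / 12.0
    slopes = math.log(2.0) / dts_years
    return CaseModelParams(
        healthy_component=healthy,
        changepoint_grid=cps,
        slope_grid=slopes,
        changepoint_weights=np.full(cps.size, 1.0 / cps.size),
        slope_weights=np.full(slopes.size, 1.0 / slopes.size),
    )


def triage_class(risk: float, thresholds: TriageThresholds | None = None) -> Triage:
    """Map a risk value onto the triage bands.

    Each cutoff is inclusive on the lower side of its band: risks equal to
    the intermediate (elevated) cutoff fall in the intermediate (elevated)
    band, and the severe band opens strictly above the severe cutoff.
    """
    thr = thresholds if thresholds is not None else TriageThresholds()
    if not (0.0 <= risk <= 1.0) or not math.isfinite(risk):
        raise ValueError(f"risk must lie in [0, 1], got {risk!r}")
    if risk < thr.intermediate_cut:
        return Triage.NORMAL
    if risk < thr.elevated_cut:
        return Triage.INTERMEDIATE
    if risk <= thr.severe_cut:
        return Triage.ELEVATED
    return Triage.SEVERE


def roca_risk(
    series: BiomarkerSeries,
    case_params: CaseModelParams,
    prior_p: float = DEFAULT_PRIOR,
    thresholds: TriageThresholds | None = None,
) -> RiskResult:
    """Posterior risk of ovarian cancer from a serial CA-125 profile.

    Combines the healthy and case marginal likelihoods with the prior in
    log-odds space, so the result is monotone in the log Bayes factor and
    free of underflow for any positive marker values.
    """
    if not (0.0 <= prior_p <= 1.0):
        raise ValueError(f"prior_p must lie in [0, 1], got {prior_p!r}")
    llh = log_marginal_flat(series, case_params.healthy_component)
    llc = log_marginal_changepoint(series, case_params)
    if prior_p == 0.0:
        risk = 0.0
    elif prior_p == 1.0:
        risk = 1.0
    else:
        risk = float(expit(logit(prior_p) + llc - llh))
    return RiskResult(
        risk=risk,
        log_lik_healthy=llh,
        log_lik_case=llc,
        triage=triage_class(risk, thresholds),
    )


def annual_risk(
    series: BiomarkerSeries,
    healthy: HealthyModelParams | None = None,
    prior_p: float = DEFAULT_PRIOR,
    thresholds: TriageThresholds | None = None,
) -> RiskResult:
    """Risk under the default change-point grid anchored at the last sample."""
    params = default_case_params(
        float(series.times[-1]), healthy if healthy is not None else HealthyModelParams()
    )
    return roca_risk(series, params, prior_p, thresholds)
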