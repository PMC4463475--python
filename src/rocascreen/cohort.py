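"""Synthetic screening cohorts with the serial structure the model assumes.

Controls follow the flat hierarchical lognormal model (stable woman-specific
baseline plus within-woman noise).  Cases acquire a latent onset drawn from
an exponential waiting time at the configured annual incidence; after onset
the log marker rises linearly at a per-case slope drawn from a doubling-time
distribution, except for a marker-negative fraction whose CA-125 never
departs from baseline (these drive interval cancers and bound attainable
sensitivity).  Clinical presentation happens when the latent marker path
crosses a symptomatic threshold (marker-negative cases present a fixed
preclinical window after onset).  Transvaginal scan readings are sampled
with imperfect sensitivity that improves with time since onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .model import BiomarkerSeries, HealthyModelParams
from .protocol import ScanResult


@dataclass(frozen=True)
class CaseKinetics:
    """Post-onset marker kinetics.

    ``doubling_time_months`` bounds a log-uniform distribution of serum
    log CA-125 doubling times.  Aggressive ovarian tumours double in
    volume roughly every 2.5 months, but the serum marker lags tumour
    burden; the default 3-18 month range yields the observed mixture of
    rapid risers and slow risers that are only caught through repeat
    testing while still in the normal range.
    ``preclinical_window_years`` is the onset-to-symptoms sojourn used for
    marker-negative cases.  ``marker_negative_fraction`` is the share of
    cases whose CA-125 stays flat.
    """

    doubling_time_months: tuple[float, float] = (3.0, 18.0)
    preclinical_window_years: float = 1.5
    marker_negative_fraction: float = 0.13

    def __post_init__(self) -> None:
        lo, hi = self.doubling_time_months
        if not (0 < lo <= hi):
            raise ValueError("doubling times must be positive and ordered")
        if not (0.0 <= self.marker_negative_fraction <= 1.0):
            raise ValueError("marker_negative_fraction must lie in [0, 1]")
        if self.preclinical_window_years <= 0:
            raise ValueError("preclinical_window_years must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated annual-screening cohort.

    Defaults mirror the trial setting: seven annual screening rounds
    (the median number of incidence screens), an annual iEOC incidence of
    1/1,915 woman-years, control trajectories from the default flat model
    (median CA-125 14 U/mL), and a symptomatic presentation threshold of
    500 U/mL on the latent (noise-free) marker path.  TVS sensitivity is
    0.6 within a year of onset and 0.9 beyond, specificity 0.985,
    unsatisfactory-scan rate 0.03.
    """

    n_women: int = 20000
    years_of_screening: int = 7
    annual_incidence: float = 1.0 / 1915.0
    control_params: HealthyModelParams = field(default_factory=HealthyModelParams)
    kinetics: CaseKinetics = field(default_factory=CaseKinetics)
    clinical_threshold: float = 500.0
    tvs_sensitivity_early: float = 0.6
    tvs_sensitivity_late: float = 0.9
    tvs_specificity: float = 0.985
    tvs_unsat_rate: float = 0.03
    age_at_entry: float = 60.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_women <= 0 or self.years_of_screening <= 0:
            raise ValueError("n_women and years_of_screening must be positive")
        for name in ("annual_incidence", "tvs_sensitivity_early", "tvs_sensitivity_late",
                     "tvs_specificity", "tvs_unsat_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.clinical_threshold <= 0:
            raise ValueError("clinical_threshold must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth state of one woman (case fields are None for controls)."""

    subject_id: str
    is_case: bool
    onset_time: Optional[float] = None
    clinical_dx_time: Optional[float] = None
    type_label: Optional[str] = None
    stage_at_dx: Optional[str] = None

    def __post_init__(self) -> None:
        if self.is_case:
            if self.onset_time is None:
                raise ValueError("cases need an onset_time")
            if self.clinical_dx_time is not None and not self.clinical_dx_time > self.onset_time:
                raise ValueError("clinical_dx_time must follow onset_time")
        elif any(x is not None for x in
                 (self.onset_time, self.clinical_dx_time, self.type_label, self.stage_at_dx)):
            raise ValueError("control records must not carry case fields")


@dataclass(frozen=True)
class WomanTrajectory:
    """Latent natural-history path, used to sample the marker at any time."""

    subject_id: str
    log_baseline: float
    slope: float  # log CA-125 rise per year after onset (0 for controls)
    onset_time: float  # inf for controls and marker-negative flat paths

    def mean_log(self, t: float) -> float:
        return self.log_baseline + self.slope * max(0.0, t - self.onset_time)


@dataclass
class _Woman:
    series: BiomarkerSeries
    truth: TruthRecord
    trajectory: WomanTrajectory


@dataclass
class Cohort:
    """Container tying annual series, truth records and latent trajectories."""

    series: list
    truth: list
    trajectories: list
    config: CohortConfig

    def women(self) -> Iterator[_Woman]:
        for s, t, tr in zip(self.series, self.truth, self.trajectories):
            yield _Woman(s, t, tr)

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            (t.subject_id, t.is_case, t.onset_time, t.clinical_dx_time,
             t.type_label, t.stage_at_dx)
            for t in self.truth
        ]
        return pd.DataFrame(
            rows,
            columns=["subject_id", "is_case", "onset_time", "clinical_dx_time",
                     "type_label", "stage"],
        )


#: Share of type II (high-grade, aggressive) tumours among simulated cases,
#: matching the preponderance of high-grade serous disease in screen-detected
#: epithelial cancers.
TYPE2_FRACTION = 0.82


def stage_proxy(onset_time: float, dx_time: float) -> str:
    """Crude stage surrogate: early (I/II) within a year of onset, else late."""
    return "I-II" if dx_time - onset_time <= 1.0 else "III-IV"


def clinical_presentation_time(truth: TruthRecord, trajectory: WomanTrajectory,
                               config: CohortConfig) -> Optional[float]:
    """Time at which disease would present symptomatically without screening.

    Marker-positive cases present when the latent log path crosses
    ``log(clinical_threshold)``; marker-negative cases present a fixed
    preclinical window after onset.  Returns None when the path never
    crosses (e.g. an infinite threshold).
    """
    if not truth.is_case:
        raise ValueError("clinical_presentation_time is defined for cases only")
    onset = truth.onset_time
    if trajectory.slope == 0.0 or not math.isfinite(trajectory.onset_time):
        return onset + config.kinetics.preclinical_window_years
    log_thr = math.log(config.clinical_threshold)
    if not math.isfinite(log_thr):
        return None
    if trajectory.log_baseline >= log_thr:
        return onset
    return onset + (log_thr - trajectory.log_baseline) / trajectory.slope


def simulate_cohort(config: CohortConfig, rng: Optional[np.random.Generator] = None) -> Cohort:
    """Generate a cohort of annual CA-125 panels plus ground truth.

    Reproducible: a given ``config.seed`` (or passed generator state)
    always yields the same cohort.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_women
    years = config.years_of_screening
    h = config.control_params
    kin = config.kinetics

    theta = rng.normal(h.mu0, math.sqrt(h.tau2), n)
    if config.annual_incidence > 0:
        onset = rng.exponential(1.0 / config.annual_incidence, n)
    else:
        onset = np.full(n, math.inf)
    # disease can surface during screening or the 1-year window after the
    # last screen; later onsets are irrelevant to this cohort
    horizon = float(years)
    is_case = onset < horizon
    marker_negative = rng.random(n) < kin.marker_negative_fraction
    lo, hi = kin.doubling_time_months
    dt_months = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
    slope = math.log(2.0) * 12.0 / dt_months
    type2 = rng.random(n) < TYPE2_FRACTION

    times = np.arange(years, dtype=float)
    eps = rng.normal(0.0, math.sqrt(h.sigma2), (n, years))
    mean_log = theta[:, None] + np.zeros((n, years))
    rise_mask = is_case & ~marker_negative
    if rise_mask.any():
        dt_from_onset = np.maximum(0.0, times[None, :] - onset[:, None])
        mean_log = mean_log + np.where(rise_mask[:, None], slope[:, None] * dt_from_onset, 0.0)
    values = np.exp(mean_log + eps)

    width = len(str(n - 1))
    series_list = []
    truth_list = []
    traj_list = []
    for i in range(n):
        sid = f"W{i:0{width}d}"
        series_list.append(BiomarkerSeries(sid, times, values[i], config.age_at_entry))
        if is_case[i]:
            traj = WomanTrajectory(
                sid,
                float(theta[i]),
                0.0 if marker_negative[i] else float(slope[i]),
                math.inf if marker_negative[i] else float(onset[i]),
            )
            truth = TruthRecord(sid, True, float(onset[i]), None,
                                "typeII" if type2[i] else "typeI", None)
            dx = clinical_presentation_time(truth, traj, config)
            truth = TruthRecord(
                sid, True, float(onset[i]), dx,
                truth.type_label,
                stage_proxy(float(onset[i]), dx) if dx is not None else None,
            )
        else:
            traj = WomanTrajectory(sid, float(theta[i]), 0.0, math.inf)
            truth = TruthRecord(sid, False)
        truth_list.append(truth)
        traj_list.append(traj)
    return Cohort(series_list, truth_list, traj_list, config)


def scan_sampler(truth: TruthRecord, time: float, config: CohortConfig,
                 rng: np.random.Generator) -> ScanResult:
    """Sample one transvaginal scan reading.

    Unsatisfactory scans occur independently at ``tvs_unsat_rate``;
    otherwise cases past onset read abnormal with the early/late
    sensitivity and everyone else with one minus specificity.
    """
    if rng.random() < config.tvs_unsat_rate:
        return ScanResult.UNSATISFACTORY
    if truth is not None and truth.is_case and truth.onset_time is not None \
            and truth.onset_time <= time:
        sens = (config.tvs_sensitivity_early
                if time - truth.onset_time <= 1.0 else config.tvs_sensitivity_late)
        p_abnormal = sens
    else:
        p_abnormal = 1.0 - config.tvs_specificity
    return ScanResult.ABNORMAL if rng.random() < p_abnormal else ScanResult.NORMAL


def make_marker_sampler(trajectory: WomanTrajectory, config: CohortConfig,
                        rng: np.random.Generator):
    """Closure drawing fresh CA-125 values on the woman's latent path."""
    sigma = math.sqrt(config.control_params.sigma2)

    def sample(t: float) -> float:
        return float(np.exp(trajectory.mean_log(t) + rng.normal(0.0, sigma)))

    return sample


def make_scan_sampler(truth: TruthRecord, config: CohortConfig, rng: np.random.Generator):
    def sample(t: float) -> ScanResult:
        return scan_sampler(truth, t, config, rng)

    return sample
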