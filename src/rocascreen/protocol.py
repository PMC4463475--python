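"""Multimodal screening protocol: a deterministic triage state machine.

An annual screening episode starts with a level I screen (CA-125 alone,
interpreted as a risk by the serial model).  Depending on the triage band
the woman is returned to annual screening, recalled for a repeat level I
screen in 12 weeks, or recalled for a level II screen (CA-125 plus
transvaginal scan, TVS) in 6 weeks.  At level II, a normal scan with
normal/intermediate risk returns her to annual screening; elevated risk
with a normal scan, or an unsatisfactory scan irrespective of risk, leads
to one repeat level II screen in 6 weeks; an abnormal scan irrespective of
risk leads to clinical evaluation.  Severe risk (> 1/5) carries a surgery
recommendation irrespective of scan findings.  Every episode terminates in
return-to-annual, surgery, or an incomplete episode.

Risk is recomputed on the full accumulated serial profile at every repeat,
so a rise between the annual draw and a repeat draw raises the triage band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_PRIOR,
    BiomarkerSeries,
    HealthyModelParams,
    RiskResult,
    Triage,
    TriageThresholds,
    annual_risk,
)

WEEKS_PER_YEAR = 52.18


class ScanResult(str, Enum):
    """Transvaginal scan reading."""

    NORMAL = "Normal"
    ABNORMAL = "Abnormal"
    UNSATISFACTORY = "Unsatisfactory"


class EventKind(str, Enum):
    LEVEL1 = "LevelI"
    REPEAT_LEVEL1 = "RepeatLevelI"
    LEVEL2 = "LevelII"
    REPEAT_LEVEL2 = "RepeatLevelII"
    CLINICAL_EVALUATION = "ClinicalEvaluation"


class Action(str, Enum):
    RETURN_TO_ANNUAL = "ReturnToAnnual"
    REPEAT_LEVEL1 = "RepeatLevelI"
    LEVEL2 = "LevelII"
    REPEAT_LEVEL2 = "RepeatLevelII"
    CLINICAL_EVALUATION = "ClinicalEvaluation"


class Terminal(str, Enum):
    RETURN_TO_ANNUAL = "ReturnToAnnual"
    SURGERY = "Surgery"
    INCOMPLETE = "Incomplete"


@dataclass(frozen=True)
class Decision:
    """Outcome of a triage decision; ``surgery_recommended`` marks the
    severe-risk rule (surgery irrespective of scan findings)."""

    action: Action
    severe: bool = False
    surgery_recommended: bool = False


@dataclass
class Event:
    time: float
    kind: EventKind
    ca125: Optional[float] = None
    risk: Optional[RiskResult] = None
    scan: Optional[ScanResult] = None


@dataclass
class ScreenEpisode:
    """Auditable event log of one annual screening episode."""

    subject_id: str
    anchor_time: float
    events: list = field(default_factory=list)
    terminal: Optional[Terminal] = None
    completed: bool = False

    @property
    def annual_risk(self) -> RiskResult:
        return self.events[0].risk

    @property
    def annual_ca125(self) -> float:
        return self.events[0].ca125

    @property
    def last_test_time(self) -> float:
        """Time of the last CA-125 assay or scan in the episode."""
        return max(e.time for e in self.events if e.ca125 is not None or e.scan is not None)

    @property
    def end_time(self) -> float:
        return self.events[-1].time


@dataclass(frozen=True)
class ProtocolConfig:
    """Delays, limits and risk-model settings of the screening protocol.

    Delays are in weeks (12 to a repeat level I, 6 to a level II and to its
    repeat, 8 from clinical referral to disposition, matching the median
    screen-to-surgery interval).  ``incomplete_rate`` is the per-episode
    probability that an episode is abandoned (deaths, withdrawals,
    oophorectomy for other disease), taken from the trial's 1,085 of
    296,911 incomplete episodes.  ``no_findings_return_prob`` is the
    probability that a clinically evaluated woman without detectable
    disease or an abnormal scan is returned to annual screening rather
    than operated on.
    """

    thresholds: TriageThresholds = field(default_factory=TriageThresholds)
    healthy: HealthyModelParams = field(default_factory=HealthyModelParams)
    prior_p: float = DEFAULT_PRIOR
    repeat_l1_delay_weeks: float = 12.0
    l2_delay_weeks: float = 6.0
    repeat_l2_delay_weeks: float = 6.0
    clinical_delay_weeks: float = 8.0
    max_repeat_l1: int = 1
    max_repeat_l2: int = 1
    incomplete_rate: float = 1085.0 / 296911.0
    no_findings_return_prob: float = 1.0

    def __post_init__(self) -> None:
        for name in ("repeat_l1_delay_weeks", "l2_delay_weeks", "repeat_l2_delay_weeks",
                     "clinical_delay_weeks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("incomplete_rate", "no_findings_return_prob", "prior_p"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


def level1_decision(risk_result: RiskResult) -> Decision:
    """Triage after a level I (CA-125 only) screen."""
    t = risk_result.triage
    if t is Triage.NORMAL:
        return Decision(Action.RETURN_TO_ANNUAL)
    if t is Triage.INTERMEDIATE:
        return Decision(Action.REPEAT_LEVEL1)
    if t is Triage.ELEVATED:
        return Decision(Action.LEVEL2)
    return Decision(Action.LEVEL2, severe=True)


def level2_decision(risk_result: RiskResult, scan: ScanResult, is_repeat: bool) -> Decision:
    """Triage after a level II (CA-125 plus TVS) screen.

    ``is_repeat`` marks that this screen already is the repeat tier, in
    which case a would-be repeat becomes a forced clinical referral.
    """
    t = risk_result.triage
    if t is Triage.SEVERE:
        return Decision(Action.CLINICAL_EVALUATION, severe=True, surgery_recommended=True)
    if scan is ScanResult.ABNORMAL:
        return Decision(Action.CLINICAL_EVALUATION)
    if scan is ScanResult.UNSATISFACTORY:
        if is_repeat:
            return Decision(Action.CLINICAL_EVALUATION)
        return Decision(Action.REPEAT_LEVEL2)
    # normal scan
    if t in (Triage.NORMAL, Triage.INTERMEDIATE):
        return Decision(Action.RETURN_TO_ANNUAL)
    if is_repeat:
        return Decision(Action.CLINICAL_EVALUATION)
    return Decision(Action.REPEAT_LEVEL2)


def _detectable(truth_state, time: float) -> bool:
    """Whether simulated disease is present (past onset) at ``time``."""
    if truth_state is None or not getattr(truth_state, "is_case", False):
        return False
    onset = getattr(truth_state, "onset_time", None)
    return onset is not None and onset <= time


def run_episode(
    series_to_date: BiomarkerSeries,
    truth_state,
    config: ProtocolConfig,
    marker_sampler: Callable[[float], float],
    scan_sampler: Callable[[float], ScanResult],
    rng: np.random.Generator,
) -> ScreenEpisode:
    """Run one annual screening episode to its terminal state.

    ``series_to_date`` must end with the annual (level I) CA-125 sample;
    ``marker_sampler(t)`` supplies repeat CA-125 draws and
    ``scan_sampler(t)`` TVS readings on demand.  The accumulated series
    (annual history plus within-episode repeats) drives every risk
    recomputation.
    """
    anchor = float(series_to_date.times[-1])
    series = series_to_date
    risk = annual_risk(series, config.healthy, config.prior_p, config.thresholds)
    ep = ScreenEpisode(subject_id=series.subject_id, anchor_time=anchor)
    ep.events.append(Event(anchor, EventKind.LEVEL1, ca125=float(series.values[-1]), risk=risk))

    if rng.random() < config.incomplete_rate:
        ep.terminal = Terminal.INCOMPLETE
        ep.completed = False
        return ep

    t = anchor
    decision = level1_decision(risk)
    n_repeat_l1 = 0
    while decision.action is Action.REPEAT_LEVEL1:
        t += config.repeat_l1_delay_weeks / WEEKS_PER_YEAR
        try:
            value = marker_sampler(t)
        except Exception:
            ep.terminal = Terminal.INCOMPLETE
            return ep
        series = series.extended(t, value)
        risk = annual_risk(series, config.healthy, config.prior_p, config.thresholds)
        ep.events.append(Event(t, EventKind.REPEAT_LEVEL1, ca125=value, risk=risk))
        n_repeat_l1 += 1
        decision = level1_decision(risk)
        if decision.action is Action.REPEAT_LEVEL1 and n_repeat_l1 >= config.max_repeat_l1:
            # persistent intermediate risk with no rise: back to annual screening
            decision = Decision(Action.RETURN_TO_ANNUAL)

    if decision.action is Action.RETURN_TO_ANNUAL:
        ep.terminal = Terminal.RETURN_TO_ANNUAL
        ep.completed = True
        return ep

    # level II tier
    n_l2 = 0
    scan = None
    while True:
        t += (config.l2_delay_weeks if n_l2 == 0 else config.repeat_l2_delay_weeks) / WEEKS_PER_YEAR
        try:
            value = marker_sampler(t)
            scan = scan_sampler(t)
        except Exception:
            ep.terminal = Terminal.INCOMPLETE
            return ep
        series = series.extended(t, value)
        risk = annual_risk(series, config.healthy, config.prior_p, config.thresholds)
        kind = EventKind.LEVEL2 if n_l2 == 0 else EventKind.REPEAT_LEVEL2
        ep.events.append(Event(t, kind, ca125=value, risk=risk, scan=scan))
        d2 = level2_decision(risk, scan, is_repeat=n_l2 >= config.max_repeat_l2)
        n_l2 += 1
        if d2.action is Action.REPEAT_LEVEL2:
            continue
        break

    if d2.action is Action.RETURN_TO_ANNUAL:
        ep.terminal = Terminal.RETURN_TO_ANNUAL
        ep.completed = True
        return ep

    # clinical evaluation and disposition
    t += config.clinical_delay_weeks / WEEKS_PER_YEAR
    ep.events.append(Event(t, EventKind.CLINICAL_EVALUATION, risk=risk))
    if d2.surgery_recommended or scan is ScanResult.ABNORMAL or _detectable(truth_state, t):
        ep.terminal = Terminal.SURGERY
    elif rng.random() < config.no_findings_return_prob:
        ep.terminal = Terminal.RETURN_TO_ANNUAL
    else:
        ep.terminal = Terminal.SURGERY
    ep.completed = True
    return ep


LOG_COLUMNS = [
    "subject_id",
    "episode_index",
    "event_time_years",
    "event_kind",
    "ca125",
    "risk",
    "triage",
    "scan_status",
    "terminal",
]


def episodes_to_log(episodes: Sequence[tuple[int, ScreenEpisode]]) -> pd.DataFrame:
    """Flatten (episode_index, episode) pairs into the event-level log table."""
    rows = []
    for idx, ep in episodes:
        for e in ep.events:
            rows.append(
                (
                    ep.subject_id,
                    idx,
                    e.time,
                    e.kind.value,
                    e.ca125 if e.ca125 is not None else np.nan,
                    e.risk.risk if e.risk is not None else np.nan,
                    e.risk.triage.value if e.risk is not None else "",
                    e.scan.value if e.scan is not None else "",
                    ep.terminal.value,
                )
            )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


@dataclass
class TrialRun:
    """Result of screening a cohort: episode objects plus flat tables."""

    episodes: list
    log: pd.DataFrame
    summary: pd.DataFrame


def run_trial(cohort, config: ProtocolConfig, rng: np.random.Generator) -> TrialRun:
    """Screen a whole cohort, one episode per woman-year until censoring.

    ``cohort`` is a :class:`rocascreen.cohort.Cohort` (annual series, truth
    records and latent trajectories).  Episodes stop for a woman after
    screen-positive surgery (bilateral oophorectomy ends screening whatever
    the pathology) or once her disease presents clinically between screens;
    no episode is generated after diagnosis.  Deterministic given the
    generator state.
    """
    from .cohort import make_marker_sampler, make_scan_sampler  # local import, no cycle at load

    episodes: list[tuple[int, ScreenEpisode]] = []
    summary_rows = []
    for woman in cohort.women():
        series, truth, traj = woman.series, woman.truth, woman.trajectory
        marker_sampler = make_marker_sampler(traj, cohort.config, rng)
        scan_sampler = make_scan_sampler(truth, cohort.config, rng)
        hist_t: list[float] = []
        hist_v: list[float] = []
        presentation = truth.clinical_dx_time if truth.is_case else None
        for k in range(len(series)):
            t_k = float(series.times[k])
            if presentation is not None and presentation <= t_k:
                break  # clinical (interval) presentation pre-empts this screen
            hist_t.append(t_k)
            hist_v.append(float(series.values[k]))
            base = BiomarkerSeries(series.subject_id, np.array(hist_t), np.array(hist_v),
                                   series.age_at_entry)
            ep = run_episode(base, truth, config, marker_sampler, scan_sampler, rng)
            # repeat draws become part of the woman's serial profile
            for e in ep.events[1:]:
                if e.ca125 is not None:
                    hist_t.append(e.time)
                    hist_v.append(e.ca125)
            episodes.append((k, ep))
            summary_rows.append(
                (
                    series.subject_id,
                    k,
                    ep.anchor_time,
                    ep.annual_ca125,
                    ep.annual_risk.risk,
                    ep.annual_risk.triage.value,
                    len(ep.events),
                    ep.last_test_time,
                    ep.terminal.value,
                    ep.end_time if ep.terminal is Terminal.SURGERY else np.nan,
                )
            )
            if ep.terminal is Terminal.SURGERY:
                break
    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "subject_id",
            "episode_index",
            "anchor_time",
            "annual_ca125",
            "annual_risk",
            "annual_triage",
            "n_events",
            "last_test_time",
            "terminal",
            "surgery_time",
        ],
    )
    return TrialRun(episodes=episodes, log=episodes_to_log(episodes), summary=summary)
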