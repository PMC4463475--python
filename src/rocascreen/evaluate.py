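"""Screening performance evaluation: confusion counts, CIs, ROC and DeLong.

A screen is positive when it culminates in surgery.  A true positive is a
screen-positive surgery finding target-category disease; an interval
(screen-negative) cancer is one diagnosed clinically within the follow-up
window (default one year) of the woman's last screening test after she was
returned to annual screening; diagnoses beyond the window are censored.
Specificity uses cancer-free screening episodes (woman-years) as the
denominator.  ROC curves compare one score per episode — the serial-model
risk versus the raw annual CA-125 — and paired AUCs are tested with the
DeLong structural-components estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

CATEGORIES = ("iEOC", "borderline", "nonepithelial", "PPC", "other")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, as used for printed percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class OutcomeTable:
    """Confusion-style counts over a body of screening episodes."""

    n_episodes: int
    n_surgeries: int
    screen_detected: dict
    interval: dict
    records: Optional[pd.DataFrame] = None  # per-episode scores/labels for ROC work

    def __post_init__(self) -> None:
        self.screen_detected = {c: int(self.screen_detected.get(c, 0)) for c in CATEGORIES}
        self.interval = {c: int(self.interval.get(c, 0)) for c in CATEGORIES}
        if self.n_episodes < 0 or self.n_surgeries < 0:
            raise ValueError("counts must be non-negative")
        if any(v < 0 for v in self.screen_detected.values()) or \
                any(v < 0 for v in self.interval.values()):
            raise ValueError("category counts must be non-negative")
        if sum(self.screen_detected.values()) > self.n_surgeries:
            raise ValueError("screen-detected cancers cannot exceed surgeries")


@dataclass(frozen=True)
class Estimate:
    """A proportion (or ratio) with an optional two-sided 95% CI."""

    point: float
    lower: float = math.nan
    upper: float = math.nan
    undefined: bool = False


@dataclass
class PerformanceReport:
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    operations_per_cancer: float
    repeat_rate: Optional[float]
    tp: int
    fp: int
    fn: int
    n_surgeries: int
    n_episodes: int
    aucs: dict = field(default_factory=dict)
    delong: Optional[tuple] = None

    def to_dict(self) -> dict:
        def est(e: Estimate) -> dict:
            return {"point": e.point, "ci95": [e.lower, e.upper], "undefined": e.undefined}

        out = {
            "sensitivity": est(self.sensitivity),
            "specificity": est(self.specificity),
            "ppv": est(self.ppv),
            "operations_per_cancer": self.operations_per_cancer,
            "repeat_rate": self.repeat_rate,
            "counts": {
                "tp": self.tp, "fp": self.fp, "fn": self.fn,
                "surgeries": self.n_surgeries, "episodes": self.n_episodes,
            },
            "aucs": self.aucs,
        }
        if self.delong is not None:
            a, b, v, z, p = self.delong
            out["delong"] = {"auc_a": a, "auc_b": b, "var_diff": v, "z": z, "p": p}
        return out

    def __str__(self) -> str:
        def pct(e: Estimate) -> str:
            if e.undefined:
                return "undefined"
            return f"{100 * e.point:.1f}% (95% CI {100 * e.lower:.1f} to {100 * e.upper:.1f})"

        lines = [
            f"episodes            {self.n_episodes}",
            f"surgeries           {self.n_surgeries}",
            f"sensitivity         {pct(self.sensitivity)}",
            f"specificity         {pct(self.specificity)}",
            f"PPV                 {pct(self.ppv)}",
            f"operations/cancer   {self.operations_per_cancer:.1f}"
            if math.isfinite(self.operations_per_cancer) else "operations/cancer   undefined",
        ]
        if self.repeat_rate is not None:
            lines.append(f"repeat rate         {100 * self.repeat_rate:.1f}%")
        for k, v in self.aucs.items():
            lines.append(f"AUC ({k})          {v:.3f}")
        if self.delong is not None:
            lines.append(f"DeLong p            {self.delong[4]:.4g}")
        return "\n".join(lines)


def binomial_ci(successes: int, n: int, level: float = 0.95,
                method: str = "clopper-pearson") -> tuple[float, float]:
    """Two-sided binomial CI; exact Clopper-Pearson by default, Wilson by flag."""
    if n <= 0 or not (0 <= successes <= n):
        raise ValueError(f"invalid counts ({successes}, {n})")
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown method {method!r}")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method=sm_method)
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def _episode_summary(log: pd.DataFrame) -> pd.DataFrame:
    """Collapse an event-level episode log to one row per episode."""
    log = log.copy()
    log["scan_status"] = log["scan_status"].fillna("")
    test_events = log[(log["ca125"].notna()) | (log["scan_status"] != "")]
    keys = ["subject_id", "episode_index"]
    first = log.drop_duplicates(keys, keep="first").set_index(keys)
    grp = log.groupby(keys, sort=False)
    out = pd.DataFrame(
        {
            "anchor_time": first["event_time_years"],
            "annual_ca125": first["ca125"],
            "annual_risk": first["risk"],
            "annual_triage": first["triage"],
            "terminal": grp["terminal"].last(),
            "end_time": grp["event_time_years"].max(),
        }
    )
    out["last_test_time"] = test_events.groupby(["subject_id", "episode_index"],
                                                sort=False)["event_time_years"].max()
    out["last_test_time"] = out["last_test_time"].fillna(out["anchor_time"])
    return out.reset_index()


def classify_outcomes(episode_log: pd.DataFrame, truth: pd.DataFrame,
                      window_years: float = 1.0) -> OutcomeTable:
    """Build an :class:`OutcomeTable` from an event-level log and truth table.

    ``truth`` needs columns subject_id, is_case, onset_time,
    clinical_dx_time (natural presentation time) and optionally
    ``category`` (defaults to iEOC for all cases).
    """
    ep = _episode_summary(episode_log)
    truth = truth.copy()
    if "category" not in truth.columns:
        truth["category"] = np.where(truth["is_case"], "iEOC", "")
    orphans = set(ep["subject_id"]) - set(truth["subject_id"])
    if orphans:
        raise ValueError(f"episode log contains subject ids missing from truth: "
                         f"{sorted(orphans)[:5]}")
    ep = ep.merge(truth, on="subject_id", how="left")

    surgeries = ep[ep["terminal"] == "Surgery"]
    n_surgeries = len(surgeries)

    # one diagnosis per woman at most: screen detection first, else clinical
    # presentation inside the censoring window of her last test
    sd_mask = (
        surgeries["is_case"].fillna(False).astype(bool)
        & (surgeries["onset_time"] <= surgeries["end_time"])
    )
    screen_detected_rows = surgeries[sd_mask]
    screen_detected_ids = set(screen_detected_rows["subject_id"])

    last_test = ep.groupby("subject_id")["last_test_time"].max()
    sd_counts = dict(screen_detected_rows["category"].value_counts())

    interval_counts: dict = {}
    dx_time = {}
    for row in screen_detected_rows.itertuples():
        dx_time[row.subject_id] = row.end_time
    case_truth = truth[truth["is_case"].fillna(False).astype(bool)]
    for row in case_truth.itertuples():
        sid = row.subject_id
        if sid in screen_detected_ids or sid not in last_test.index:
            continue
        cdx = row.clinical_dx_time
        if cdx is None or (isinstance(cdx, float) and math.isnan(cdx)):
            continue
        if cdx <= last_test[sid] + window_years:
            interval_counts[row.category] = interval_counts.get(row.category, 0) + 1
            dx_time[sid] = cdx
        # diagnoses beyond the window are censored: neither TP nor FN

    # per-episode scores and labels for ROC construction: an episode is a
    # cancer episode when linked to a diagnosis within the window
    ep["dx_time"] = ep["subject_id"].map(dx_time)
    ep["label"] = (
        ep["dx_time"].notna()
        & (ep["dx_time"] >= ep["anchor_time"])
        & (ep["dx_time"] <= ep["anchor_time"] + window_years)
    ).astype(int)
    records = ep[["subject_id", "episode_index", "anchor_time", "annual_ca125",
                  "annual_risk", "annual_triage", "terminal", "label"]].copy()

    return OutcomeTable(
        n_episodes=len(ep),
        n_surgeries=n_surgeries,
        screen_detected=sd_counts,
        interval=interval_counts,
        records=records,
    )


def compute_performance(table: OutcomeTable,
                        target_categories: Sequence[str] = ("iEOC",),
                        window_cases: Optional[int] = None,
                        ci_method: str = "clopper-pearson") -> PerformanceReport:
    """Sensitivity, specificity, PPV and operations per cancer with 95% CIs.

    ``window_cases`` (TP + FN) defaults to the table's own counts; the
    specificity denominator is cancer-free episodes, n_episodes minus
    window cases.
    """
    tp = sum(table.screen_detected[c] for c in target_categories)
    fn = sum(table.interval[c] for c in target_categories)
    if window_cases is None:
        window_cases = tp + fn
    fp = table.n_surgeries - tp
    noncase_episodes = table.n_episodes - window_cases

    def prop(k: int, n: int) -> Estimate:
        if n <= 0:
            return Estimate(math.nan, undefined=True)
        lo, hi = binomial_ci(k, n, method=ci_method)
        return Estimate(k / n, lo, hi)

    sens = prop(tp, tp + fn)
    spec = prop(noncase_episodes - fp, noncase_episodes)
    ppv = prop(tp, table.n_surgeries)
    ops = table.n_surgeries / tp if tp > 0 else math.nan
    repeat_rate = None
    if table.records is not None and len(table.records):
        repeat_rate = float((table.records["annual_triage"] != "Normal").mean())
    return PerformanceReport(
        sensitivity=sens, specificity=spec, ppv=ppv,
        operations_per_cancer=ops, repeat_rate=repeat_rate,
        tp=tp, fp=fp, fn=fn,
        n_surgeries=table.n_surgeries, n_episodes=table.n_episodes,
    )


def _check_binary(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not (pos.any() and neg.any()) or not np.all(pos | neg):
        raise ValueError("labels must be binary with both classes present")
    return pos, neg


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC points (thresholds, FPR, TPR) over all distinct score cutoffs.

    Ties are grouped; the curve starts at (0, 0) with threshold +inf and
    ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_binary(labels)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = pos[order].astype(float)
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1.0 - y)[distinct]
    thresholds = np.r_[np.inf, s[distinct]]
    tpr = np.r_[0.0, tps / pos.sum()]
    fpr = np.r_[0.0, fps / neg.sum()]
    return thresholds, fpr, tpr


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with half credit for ties (= trapezoidal ROC area)."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_binary(labels)
    r = rankdata(scores)
    m = int(pos.sum())
    n = int(neg.sum())
    return float((r[pos].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_components(scores: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """Structural components (midrank placements) of one score vector."""
    x = scores[pos]
    y = scores[neg]
    m, n = x.size, y.size
    all_r = rankdata(np.r_[x, y])
    v10 = (all_r[:m] - rankdata(x)) / n
    v01 = 1.0 - (all_r[m:] - rankdata(y)) / m
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float, float]:
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns (auc_a, auc_b, variance of the difference, z, two-sided p).
    Both score vectors must be evaluated on the same subjects.  When both
    scores are identical the difference is exactly zero and p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    pos, neg = _check_binary(labels)
    v10a, v01a = _delong_components(scores_a, pos, neg)
    v10b, v01b = _delong_components(scores_b, pos, neg)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    s = s10 / m + s01 / n
    var = float(s[0, 0] + s[1, 1] - 2.0 * s[0, 1])
    diff = auc_a - auc_b
    if var <= 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    p = 1.0 if (var <= 0.0 and diff == 0.0) else float(2.0 * norm.sf(abs(z)))
    return auc_a, auc_b, var, z, p


def fixed_cutoff_performance(annual_values, labels,
                             cutoffs: Sequence[float] = (35.0, 30.0, 22.0)) -> dict:
    """Sensitivity and repeat-rate of single-threshold rules.

    ``annual_values`` holds one annual CA-125 per episode and ``labels``
    marks cancer-linked episodes.  Sensitivity is the fraction of
    cancer-linked annual screens exceeding the cutoff; the repeat rate is
    the fraction of all screens exceeding it (screens that a fixed rule
    would recall).
    """
    values = np.asarray(annual_values, dtype=float)
    labels = np.asarray(labels)
    if values.size == 0:
        raise ValueError("no annual values supplied")
    if values.shape != labels.shape:
        raise ValueError("annual_values and labels must have equal length")
    case = labels == 1
    out = {}
    for c in cutoffs:
        flagged = values > c
        out[float(c)] = {
            "sensitivity": float(flagged[case].mean()) if case.any() else math.nan,
            "repeat_rate": float(flagged.mean()),
        }
    return out


def plot_roc(curves: dict, path: str) -> None:
    """Write a ROC figure; ``curves`` maps name -> (fpr, tpr) arrays."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (fpr, tpr) in curves.items():
        ax.plot(fpr, tpr, label=name)
    ax.plot([0, 1], [0, 1], ls=":", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
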