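"""Bundled fixture of the trial's printed outcome counts, and the worked
arithmetic that reproduces its printed performance figures.

The fixture ships as a versioned JSON data file so the provenance note of
each count travels with the numbers.  :func:`reproduce_fixture` recomputes
every printed percentage and ratio from the raw counts through the same
performance code used for simulated cohorts, and compares after half-up
rounding to one decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .evaluate import OutcomeTable, binomial_ci, compute_performance, round_half_up


@dataclass(frozen=True)
class TrialFixture:
    episodes: int
    volunteers: int
    surgeries: int
    screen_detected: dict
    interval: dict
    repeat_recommendations: dict
    flagged_cases: dict
    benign_surgeries: int
    surgical_complications: int
    early_stage_iEOC: int
    type2_iEOC: int
    clinical_evaluations: int
    incomplete_episodes: int
    printed: dict

    @property
    def ieoc_within_1yr(self) -> int:
        return self.screen_detected["iEOC"] + self.interval["iEOC"]

    def outcome_table(self) -> OutcomeTable:
        return OutcomeTable(
            n_episodes=self.episodes,
            n_surgeries=self.surgeries,
            screen_detected=self.screen_detected,
            interval=self.interval,
        )


def load_trial_fixture() -> TrialFixture:
    """Load the bundled counts and assert their internal consistency."""
    with resources.files("rocascreen.data").joinpath("trial_counts.json").open() as fh:
        raw = json.load(fh)

    def counts(d: dict) -> dict:
        return {k: v for k, v in d.items() if k != "note"}

    fix = TrialFixture(
        episodes=raw["episodes"],
        volunteers=raw["volunteers"],
        surgeries=raw["surgeries"],
        screen_detected=counts(raw["screen_detected"]),
        interval=counts(raw["interval"]),
        repeat_recommendations=counts(raw["repeat_recommendations"]),
        flagged_cases=counts(raw["flagged_cases"]),
        benign_surgeries=raw["benign_surgeries"],
        surgical_complications=raw["surgical_complications"],
        early_stage_iEOC=raw["early_stage_iEOC"],
        type2_iEOC=raw["type2_iEOC"],
        clinical_evaluations=raw["clinical_evaluations"],
        incomplete_episodes=raw["incomplete_episodes"],
        printed=raw["printed"],
    )
    sd = fix.screen_detected
    # 133 iEOC + 17 borderline + 4 nonepithelial = 154 ovarian/tubal screen positives
    if sd["iEOC"] + sd["borderline"] + sd["nonepithelial"] != 154:
        raise ValueError("fixture inconsistency: ovarian/tubal screen positives != 154")
    if fix.ieoc_within_1yr != 155:
        raise ValueError("fixture inconsistency: iEOCs within one year != 155")
    if fix.benign_surgeries > fix.surgeries:
        raise ValueError("fixture inconsistency: benign surgeries exceed surgeries")
    for d in (fix.screen_detected, fix.interval, fix.repeat_recommendations,
              fix.flagged_cases):
        if any(v < 0 for v in d.values()):
            raise ValueError("fixture inconsistency: negative count")
    return fix


def reproduce_fixture(fix: TrialFixture | None = None) -> list[dict]:
    """Recompute the printed performance figures from the raw counts.

    Returns one row per figure: name, computed value (half-up rounded to
    one decimal where the print is a percentage), the printed value, and
    whether they agree exactly.
    """
    fix = fix if fix is not None else load_trial_fixture()
    rows: list[dict] = []

    def add(name: str, computed: float, printed, n: int) -> None:
        ok = computed == printed if not isinstance(printed, list) else computed == tuple(printed)
        rows.append({"name": name, "computed": computed, "printed": printed,
                     "n": n, "ok": bool(ok)})

    rep = compute_performance(fix.outcome_table(), target_categories=("iEOC",))
    add("mms_sensitivity_pct", round_half_up(100 * rep.sensitivity.point),
        fix.printed["mms_sensitivity_pct"], rep.tp + rep.fn)
    add("ppv_ieoc_pct", round_half_up(100 * rep.ppv.point),
        fix.printed["ppv_ieoc_pct"], fix.surgeries)
    add("surgeries_per_ieoc", round_half_up(rep.operations_per_cancer),
        fix.printed["surgeries_per_ieoc"], fix.surgeries)
    add("specificity_pct", round_half_up(100 * rep.specificity.point),
        fix.printed["specificity_pct"], rep.n_episodes - rep.tp - rep.fn)

    rep_ppc = compute_performance(fix.outcome_table(), target_categories=("iEOC", "PPC"))
    add("ppv_with_ppc_pct", round_half_up(100 * rep_ppc.ppv.point),
        fix.printed["ppv_with_ppc_pct"], fix.surgeries)

    n_cases = fix.ieoc_within_1yr
    add("roca_alone_sensitivity_pct",
        round_half_up(100 * fix.flagged_cases["roca"] / n_cases),
        fix.printed["roca_alone_sensitivity_pct"], n_cases)
    for c in (35, 30, 22):
        add(f"cutoff{c}_sensitivity_pct",
            round_half_up(100 * fix.flagged_cases[f"cutoff{c}"] / n_cases),
            fix.printed[f"cutoff{c}_sensitivity_pct"], n_cases)
        add(f"cutoff{c}_repeat_rate_pct",
            round_half_up(100 * fix.repeat_recommendations[f"cutoff{c}"] / fix.episodes),
            fix.printed[f"cutoff{c}_repeat_rate_pct"], fix.episodes)
    add("roca_repeat_rate_pct",
        round_half_up(100 * fix.repeat_recommendations["roca"] / fix.episodes),
        fix.printed["roca_repeat_rate_pct"], fix.episodes)

    add("early_stage_pct",
        round_half_up(100 * fix.early_stage_iEOC / fix.screen_detected["iEOC"]),
        fix.printed["early_stage_pct"], fix.screen_detected["iEOC"])
    add("type2_pct",
        round_half_up(100 * fix.type2_iEOC / fix.screen_detected["iEOC"]),
        fix.printed["type2_pct"], fix.screen_detected["iEOC"])
    add("complication_rate_pct",
        round_half_up(100 * fix.surgical_complications / fix.benign_surgeries),
        fix.printed["complication_rate_pct"], fix.benign_surgeries)
    lo, hi = binomial_ci(fix.surgical_complications, fix.benign_surgeries)
    add("complication_ci_pct",
        (round_half_up(100 * lo), round_half_up(100 * hi)),
        fix.printed["complication_ci_pct"], fix.benign_surgeries)
    return rows
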