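"""Tests for outcome classification, metrics, ROC/AUC and the DeLong test."""

import math

import numpy as np
import pandas as pd
import pytest

from oracles import (bootstrap_auc_diff_variance, enumerate_roc,
                     exact_binomial_ci, pairwise_auc)
from rocascreen.evaluate import (OutcomeTable, auc, binomial_ci,
                                 classify_outcomes, compute_performance,
                                 delong_test, fixed_cutoff_performance,
                                 roc_curve, round_half_up)
from rocascreen.fixtures import load_trial_fixture


def _log_row(sid, idx, t, kind, ca125, risk, triage, scan, terminal):
    return dict(subject_id=sid, episode_index=idx, event_time_years=t,
                event_kind=kind, ca125=ca125, risk=risk, triage=triage,
                scan_status=scan, terminal=terminal)


def _toy_log_and_truth():
    """Three cases and one control over a two-screen history.

    - "det": screen-detected at her year-1 episode (surgery finds disease).
    - "intv": returned to annual screening, presents clinically 11 months
      after her last test (interval cancer).
    - "late": presents 13 months after her last test (censored).
    - "ctrl": benign surgery (false positive).
    """
    rows = [
        _log_row("det", 0, 0.0, "LevelI", 14.0, 1e-5, "Normal", "", "ReturnToAnnual"),
        _log_row("det", 1, 1.0, "LevelI", 60.0, 0.1, "Elevated", "", "Surgery"),
        _log_row("det", 1, 1.12, "LevelII", 80.0, 0.2, "Elevated", "Abnormal", "Surgery"),
        _log_row("det", 1, 1.27, "ClinicalEvaluation", np.nan, 0.2, "Elevated", "", "Surgery"),
        _log_row("intv", 0, 0.0, "LevelI", 13.0, 1e-5, "Normal", "", "ReturnToAnnual"),
        _log_row("intv", 1, 1.0, "LevelI", 15.0, 2e-5, "Normal", "", "ReturnToAnnual"),
        _log_row("late", 0, 0.0, "LevelI", 12.0, 1e-5, "Normal", "", "ReturnToAnnual"),
        _log_row("ctrl", 0, 0.0, "LevelI", 30.0, 5e-4, "Intermediate", "", "Surgery"),
        _log_row("ctrl", 0, 0.23, "RepeatLevelI", 33.0, 2e-3, "Elevated", "", "Surgery"),
        _log_row("ctrl", 0, 0.35, "LevelII", 31.0, 2e-3, "Elevated", "Abnormal", "Surgery"),
        _log_row("ctrl", 0, 0.50, "ClinicalEvaluation", np.nan, 2e-3, "Elevated", "", "Surgery"),
    ]
    truth = pd.DataFrame(
        {
            "subject_id": ["det", "intv", "late", "ctrl"],
            "is_case": [True, True, True, False],
            "onset_time": [0.5, 0.4, 0.0, np.nan],
            # intv presents 11 months after her last test (t=1.0);
            # late presents 13 months after hers (t=0.0)
            "clinical_dx_time": [2.0, 1.0 + 11 / 12, 13 / 12, np.nan],
            "type_label": ["typeII", "typeII", "typeI", None],
            "stage": ["I-II", "III-IV", "III-IV", None],
        }
    )
    return pd.DataFrame(rows), truth


def test_classify_outcomes_toy_log():
    log, truth = _toy_log_and_truth()
    table = classify_outcomes(log, truth)
    assert table.n_episodes == 6
    assert table.n_surgeries == 2
    assert table.screen_detected["iEOC"] == 1   # det
    assert table.interval["iEOC"] == 1          # intv at 11 months
    # late presented 13 months after her last test: censored entirely
    rec = table.records.set_index(["subject_id", "episode_index"])
    assert rec.loc[("det", 1), "label"] == 1
    assert rec.loc[("det", 0), "label"] == 0
    assert rec.loc[("intv", 1), "label"] == 1
    assert rec.loc[("late", 0), "label"] == 0


def test_classify_outcomes_rejects_orphan_subjects():
    log, truth = _toy_log_and_truth()
    with pytest.raises(ValueError, match="missing from truth"):
        classify_outcomes(log, truth[truth.subject_id != "late"])


def test_compute_performance_on_toy_counts():
    table = OutcomeTable(n_episodes=1000, n_surgeries=10,
                         screen_detected={"iEOC": 4}, interval={"iEOC": 1})
    rep = compute_performance(table)
    assert rep.sensitivity.point == pytest.approx(4 / 5)
    assert rep.ppv.point == pytest.approx(0.4)
    assert rep.fp == 6
    assert rep.specificity.point == pytest.approx(1 - 6 / 995)
    assert rep.operations_per_cancer == pytest.approx(2.5)


def test_compute_performance_undefined_metrics_flagged():
    table = OutcomeTable(n_episodes=100, n_surgeries=0,
                         screen_detected={}, interval={})
    rep = compute_performance(table)
    assert rep.sensitivity.undefined
    assert rep.ppv.undefined
    assert math.isnan(rep.operations_per_cancer)


def test_outcome_table_validation():
    with pytest.raises(ValueError):
        OutcomeTable(n_episodes=10, n_surgeries=1,
                     screen_detected={"iEOC": 2}, interval={})
    with pytest.raises(ValueError):
        OutcomeTable(n_episodes=-1, n_surgeries=0, screen_detected={}, interval={})


def test_binomial_ci_against_tail_inversion_oracle():
    """Clopper-Pearson limits agree with direct root-finding on the
    binomial tails to 1e-6."""
    for k, n in ((133, 155), (20, 441), (0, 50), (50, 50), (7, 9)):
        lo, hi = binomial_ci(k, n)
        olo, ohi = exact_binomial_ci(k, n)
        assert lo == pytest.approx(olo, abs=1e-6)
        assert hi == pytest.approx(ohi, abs=1e-6)
    assert binomial_ci(0, 10)[0] == 0.0
    wilson = binomial_ci(20, 441, method="wilson")
    assert wilson != binomial_ci(20, 441)
    with pytest.raises(ValueError):
        binomial_ci(5, 0)
    with pytest.raises(ValueError):
        binomial_ci(3, 2)


def test_roc_curve_trivial_shapes():
    thr, fpr, tpr = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert (fpr[0], tpr[0]) == (0.0, 0.0)
    assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
    assert (0.0, 1.0) in set(zip(fpr, tpr))  # perfect separation corner
    assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    # all-tied scores collapse to the diagonal
    thr, fpr, tpr = roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])
    assert list(zip(fpr, tpr)) == [(0.0, 0.0), (1.0, 1.0)]
    assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5
    with pytest.raises(ValueError):
        roc_curve([0.1, 0.2], [1, 1])


def test_roc_curve_matches_threshold_enumeration(rng):
    scores = np.round(rng.random(60), 1)  # force ties
    labels = (rng.random(60) < 0.4).astype(int)
    thr, fpr, tpr = roc_curve(scores, labels)
    assert list(zip(fpr, tpr)) == enumerate_roc(scores, labels)
    assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
    # trapezoidal area equals the Mann-Whitney statistic
    assert np.trapezoid(tpr, fpr) == pytest.approx(auc(scores, labels), abs=1e-12)


def test_auc_is_pairwise_mann_whitney(rng):
    scores = np.array([0.1, 0.4, 0.4, 0.7, 0.7, 0.9])
    labels = np.array([0, 0, 1, 0, 1, 1])
    assert auc(scores, labels) == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
    assert auc(scores, 1 - labels) == pytest.approx(1 - auc(scores, labels), abs=1e-12)
    for _ in range(5):
        s = rng.random(80)
        y = (rng.random(80) < 0.5).astype(int)
        assert auc(s, y) == pytest.approx(pairwise_auc(s, y), abs=1e-12)


def test_auc_cross_checked_against_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    s = np.round(rng.normal(size=300), 1)
    y = (rng.random(300) < 0.3).astype(int)
    assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_delong_identical_scores_is_null():
    s = np.array([0.1, 0.5, 0.3, 0.9, 0.2, 0.8])
    y = np.array([0, 1, 0, 1, 0, 1])
    auc_a, auc_b, var, z, p = delong_test(s, s, y)
    assert auc_a == auc_b
    assert z == 0.0
    assert p == 1.0


def test_delong_aucs_match_auc_function(rng):
    sa = rng.normal(size=100)
    sb = rng.normal(size=100)
    y = (rng.random(100) < 0.4).astype(int)
    auc_a, auc_b, *_ = delong_test(sa, sb, y)
    assert auc_a == pytest.approx(auc(sa, y), abs=1e-12)
    assert auc_b == pytest.approx(auc(sb, y), abs=1e-12)


def test_delong_variance_close_to_bootstrap():
    """On a paired 20 vs 20 instance the DeLong variance of the AUC
    difference sits within 15% of a 10,000-replicate case/control
    bootstrap."""
    rng = np.random.default_rng(0)
    x = rng.normal(1.0, 1.0, 20)
    y = rng.normal(0.0, 1.0, 20)
    sa = np.r_[x, y]
    sb = 0.7 * sa + 0.3 * rng.normal(0.0, 1.0, 40)
    labels = np.r_[np.ones(20), np.zeros(20)]
    var = delong_test(sa, sb, labels)[2]
    var_boot = bootstrap_auc_diff_variance(sa, sb, labels, n_boot=10_000, seed=0)
    assert abs(var - var_boot) <= 0.15 * var_boot


def test_delong_detects_large_effect():
    rng = np.random.default_rng(3)
    labels = np.r_[np.ones(200), np.zeros(200)]
    informative = np.r_[rng.normal(2.0, 1.0, 200), rng.normal(0.0, 1.0, 200)]
    noise = rng.normal(size=400)
    *_, p = delong_test(informative, noise, labels)
    assert p < 1e-3
    with pytest.raises(ValueError):
        delong_test(informative[:-1], noise, labels)


def test_delong_matches_reference_r_implementation(tmp_path):
    """Cross-check z and p against the pROC package on a fixed instance."""
    import subprocess

    rng = np.random.default_rng(0)
    sa = np.r_[rng.normal(1, 1, 20), rng.normal(0, 1, 20)]
    sb = 0.7 * sa + 0.3 * rng.normal(0, 1, 40)
    labels = np.r_[np.ones(20), np.zeros(20)]
    csv = tmp_path / "scores.csv"
    np.savetxt(csv, np.c_[labels, sa, sb], delimiter=",", header="lab,a,b", comments="")
    script = (
        'suppressMessages(library(pROC));'
        f'd<-read.csv("{csv}");'
        'r<-roc.test(roc(d$lab,d$a,quiet=TRUE),roc(d$lab,d$b,quiet=TRUE),'
        'method="delong",paired=TRUE);'
        'cat(sprintf("%.12f %.12f", r$statistic, r$p.value))'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True).stdout.split()
    z_ref, p_ref = float(out[0]), float(out[1])
    *_, z, p = delong_test(sa, sb, labels)
    assert z == pytest.approx(z_ref, abs=1e-8)
    assert p == pytest.approx(p_ref, abs=1e-8)


def test_fixed_cutoff_rules():
    values = np.array([10, 20, 30, 40, 50, 60, 25, 15, 70, 80.0])
    labels = np.array([0, 0, 0, 1, 1, 0, 1, 0, 1, 1])
    out = fixed_cutoff_performance(values, labels, cutoffs=(0.0, 65.0, 35.0))
    assert out[0.0]["sensitivity"] == 1.0
    assert out[0.0]["repeat_rate"] == 1.0
    # cutoff between the two largest distinct values flags exactly those
    assert out[65.0]["repeat_rate"] == pytest.approx(0.2)
    assert out[65.0]["sensitivity"] == pytest.approx(2 / 5)
    assert out[35.0]["sensitivity"] == pytest.approx(4 / 5)
    with pytest.raises(ValueError):
        fixed_cutoff_performance([], [])


def test_round_half_up_matches_print_convention():
    assert round_half_up(81.95) == 82.0
    assert round_half_up(4.812) == 4.8
    assert round_half_up(66.45) == 66.5
    assert round_half_up(1.885) == 1.9


def test_fixture_worked_example_percentages():
    """The printed sensitivity/PPV/operations arithmetic follows from the
    fixture's raw counts through the generic performance code."""
    fix = load_trial_fixture()
    rep = compute_performance(fix.outcome_table())
    assert round_half_up(100 * rep.sensitivity.point) == 85.8
    assert round_half_up(100 * rep.ppv.point) == 20.8
    assert round_half_up(rep.operations_per_cancer) == 4.8
    rep_ppc = compute_performance(fix.outcome_table(), ("iEOC", "PPC"))
    assert round_half_up(100 * rep_ppc.ppv.point) == 22.7
    assert round_half_up(100 * rep_ppc.sensitivity.point) == 85.3
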