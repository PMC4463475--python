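"""Independent oracles used by the test suite.

Everything here is deliberately naive (Monte-Carlo integration, all-pairs
enumeration, root-finding on binomial tails, case/control bootstrap) and
shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom


def mc_marginal(times, values, mu0, tau2, sigma2, slope=0.0, changepoint=np.inf,
                n_draws=1_000_000, seed=0):
    """Monte-Carlo estimate (probability scale) of the marginal density of the
    log-values under the hierarchical model, integrating the subject baseline
    by simulation.  Importance-samples the baseline from an inflated
    Gaussian proposal centred near the data so the estimator stays sharp
    even when the prior is wide.  Returns (estimate, standard error)."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    z = np.log(np.asarray(values, dtype=float)) - mu0 - slope * np.maximum(0.0, t - changepoint)
    n = z.size
    if tau2 == 0.0:
        prop_mean, prop_var = 0.0, 1e-12  # degenerate prior: theta == 0
        theta = np.zeros(n_draws)
        log_prior_minus_prop = np.zeros(n_draws)
    else:
        prec = n / sigma2 + 1.0 / tau2
        prop_mean = (z.sum() / sigma2) / prec
        prop_var = 2.0 / prec  # inflate for heavier tails than the target
        theta = rng.normal(prop_mean, np.sqrt(prop_var), n_draws)
        log_prior_minus_prop = (
            -0.5 * theta ** 2 / tau2 - 0.5 * np.log(2.0 * np.pi * tau2)
            + 0.5 * (theta - prop_mean) ** 2 / prop_var
            + 0.5 * np.log(2.0 * np.pi * prop_var)
        )
    resid = z[None, :] - theta[:, None]
    ll = -0.5 * np.sum(resid ** 2, axis=1) / sigma2 \
        - n / 2.0 * np.log(2.0 * np.pi * sigma2) + log_prior_minus_prop
    lik = np.exp(ll)
    return float(lik.mean()), float(lik.std(ddof=1) / np.sqrt(n_draws))


def exact_binomial_ci(k, n, level=0.95):
    """Clopper-Pearson interval by direct root-finding on the binomial tails
    (no beta-quantile shortcut)."""
    alpha = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else brentq(lambda p: binom.sf(k - 1, n, p) - alpha,
                                   1e-12, 1 - 1e-12, xtol=1e-13)
    hi = 1.0 if k == n else brentq(lambda p: binom.cdf(k, n, p) - alpha,
                                   1e-12, 1 - 1e-12, xtol=1e-13)
    return lo, hi


def pairwise_auc(scores, labels):
    """All-pairs Mann-Whitney probability with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)


def enumerate_roc(scores, labels):
    """ROC points by brute-force sweep over every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pts = [(0.0, 0.0)]
    for thr in sorted(set(scores), reverse=True):
        pred = scores >= thr
        tpr = (pred & (labels == 1)).sum() / (labels == 1).sum()
        fpr = (pred & (labels == 0)).sum() / (labels == 0).sum()
        pts.append((fpr, tpr))
    return pts


def bootstrap_auc_diff_variance(scores_a, scores_b, labels, n_boot=10_000, seed=0):
    """Variance of the paired AUC difference under a stratified
    (case/control) subject bootstrap."""
    rng = np.random.default_rng(seed)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        pi = rng.choice(pos_idx, pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, neg_idx.size, replace=True)
        da = (scores_a[pi][:, None] > scores_a[ni][None, :]).mean() \
            + 0.5 * (scores_a[pi][:, None] == scores_a[ni][None, :]).mean()
        db = (scores_b[pi][:, None] > scores_b[ni][None, :]).mean() \
            + 0.5 * (scores_b[pi][:, None] == scores_b[ni][None, :]).mean()
        diffs[i] = da - db
    return float(diffs.var(ddof=1))
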