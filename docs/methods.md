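# Methods

## Risk model

The serial-risk calculation is a Bayes-factor comparison of two generative
models for a woman's log CA-125 history. Under the healthy model the log
marker is flat: y_ij = θ_i + ε_ij with θ_i ~ N(μ₀, τ²) (between-woman
baseline spread) and ε_ij ~ N(0, σ²) (within-woman assay plus biological
noise). Under the case model a linear rise at slope γ (per year of log
marker) starts at a latent change point τ: y_ij = θ_i + γ·max(0, t_ij − τ)
+ ε_ij. In both models θ_i is integrated analytically, leaving a
multivariate normal with compound-symmetry covariance σ²I + τ²J whose
determinant and inverse have closed forms, so no factorisation is needed and
series of any length evaluate in microseconds.

The case marginal is a weighted mixture over a grid of (τ, γ) cells,
combined by log-sum-exp. The default grid places change points monthly over
the five years preceding the last sample plus one cell beyond the
observation window; that beyond-window cell reduces exactly to the healthy
model, so the mixture never assigns vanishing likelihood to a
healthy-looking profile and the Bayes factor is bounded below by the cell
weight. Slopes are log-spaced over log CA-125 doubling times of 1.5 to 18
months. Weights are uniform. All computation is in natural-log space; no
other underflow guards are needed for CA-125 anywhere in [1, 10⁵] U/mL.

The posterior risk for prior p per screen is expit(logit(p) + log L_case −
log L_healthy), monotone in the log Bayes factor by construction. Triage
bands use the post-April-2005 cutoffs by default (intermediate 1/3,500,
elevated 1/1,000, severe 1/5), with the pre-2005 pair (1/1,818, 1/500)
selectable by era. Each cutoff is inclusive on the lower side of its band;
the boundary has measure zero in practice.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| μ₀ | log 14 | control median CA-125 ≈ 13.6–14 U/mL in screen-negative postmenopausal women |
| τ² | 0.18 | between-woman log variance; with σ² gives total control log-SD 0.45, under which ~2% of control screens exceed 35 U/mL — the repeat burden a 35 U/mL rule actually generates |
| σ² | 0.0225 | within-woman serial CV ≈ 15%; serial CA-125 is highly stable within a healthy woman, which is the premise of longitudinal interpretation. A substantially larger value would force the algorithm to wait for ~1-log-unit rises and push every detected case far above 35 U/mL, contradicting the observed preponderance of screen-detected cancers still in the normal range |
| prior p | 1/2,000 | ≈ annual iEOC incidence in the screened age group (1/1,915 woman-years) |
| change-point grid | monthly, last 5 y + beyond-window | covers plausible preclinical lead times at the screening cadence |
| slope grid | 8 slopes, doubling times 1.5–18 mo | brackets fast high-grade risers and slow risers caught only by repeat testing |

These are configuration, not estimates from any dataset: the package ships
no patient data and the defaults are chosen to be jointly consistent with
the printed operating characteristics of the trial setting (control median,
fraction of screens above fixed cutoffs, value distribution of detected
cases).

## Screening protocol

Annual screens run on the anniversary clock (t = 0 … Y−1 years). The level
I screen computes the risk on the woman's full accumulated serial profile —
annual draws plus any repeat draws from earlier episodes. Triage: normal →
return to annual screening; intermediate → repeat CA-125 at +12 weeks;
elevated/severe → CA-125 + transvaginal scan (TVS) at +6 weeks. At level
II: normal/intermediate risk with a normal scan returns to annual
screening; elevated risk with a normal scan, or an unsatisfactory scan at
any risk, earns one repeat level II at +6 weeks (a repeat that would repeat
again is forced to clinical evaluation); an abnormal scan at any risk goes
to clinical evaluation; severe risk carries a surgery recommendation
irrespective of scan findings. Risk is recomputed after every repeat draw,
so a rise between the annual sample and a 12-week repeat escalates the
episode.

Decisions the protocol description leaves open, resolved here as
configuration with the stated defaults:

- **Repeated level I screens.** One repeat before forced disposition
  (`max_repeat_l1 = 1`); persistent intermediate risk without a rise
  returns to annual screening rather than looping. The trial occasionally
  allowed a second repeat; one tier keeps every episode within a bounded
  event count and is configurable.
- **Clinical-evaluation disposition.** Real disposition was clinician
  judgement. In simulation, women with an abnormal scan, a severe-risk
  recommendation, or simulated disease present at evaluation time proceed
  to surgery; everyone else returns to annual screening with probability
  `no_findings_return_prob` (default 1.0). Time from referral to
  disposition defaults to 8 weeks, the median screen-to-surgery interval.
- **Incomplete episodes.** Drawn per episode at rate 1,085/296,911
  (deaths, withdrawals, oophorectomy for other disease), without
  subdividing reasons.
- **Time bookkeeping.** Weeks, converted at 52.18 weeks/year.

Screening for a woman ends at screen-positive surgery (bilateral
oophorectomy ends participation whatever the pathology) or when her disease
presents clinically between screens; no episode is generated after
diagnosis.

## Synthetic cohorts

Controls follow the healthy model exactly. Case onsets are exponential
waiting times at the configured annual incidence (default 1/1,915); onsets
beyond the screening horizon are treated as non-cases. After onset the
latent log marker rises linearly with a per-case slope drawn log-uniformly
over doubling times of 3–18 months, except a marker-negative fraction
(default 0.13) whose CA-125 never departs from baseline — these bound the
attainable sensitivity near the mid-80s and generate interval cancers. The
marker doubling range is deliberately slower than the ~2.5-month *tumour
volume* doubling of aggressive disease: serum CA-125 lags tumour burden,
and the slower tail is what produces the clinically central phenomenon of
cases detected through repeat testing while still under 35 U/mL.

Clinical presentation occurs when the latent (noise-free) path crosses a
symptomatic threshold, default 500 U/mL — a level typical of symptomatic
advanced disease; marker-negative cases present a fixed preclinical window
(default 1.5 years) after onset. The stage label is a crude surrogate —
early (I/II) if diagnosis falls within a year of onset, late (III/IV)
otherwise — used only for qualitative earlier-detection patterns. Type II
(high-grade) labels are assigned to 82% of cases, the observed share among
screen-detected invasive cancers. TVS readings are sampled with sensitivity
0.6 within a year of onset and 0.9 beyond (imaging misses small early
tumours), specificity 0.985, and a 3% unsatisfactory rate drawn first and
independently.

## Evaluation

A screen is positive when the episode culminates in surgery. True positives
are screen-positive surgeries with disease present (category iEOC in
simulation); interval (screen-negative) cancers are clinical presentations
within one year of the woman's last screening test after a return to annual
screening; later presentations are censored — neither true positive nor
false negative. Specificity uses cancer-free woman-year episodes as the
denominator, the only convention consistent with reporting it alongside a
woman-years count. Sensitivity = TP/(TP+FN), PPV = TP/surgeries, operations
per cancer = surgeries/TP. Binomial CIs are exact Clopper–Pearson by
default (this is the method that reproduces the printed complication-rate
interval digit for digit), Wilson by flag; both delegate to statsmodels.

ROC comparison uses one score per woman-year episode — the annual serial
risk versus the annual CA-125 — with cancer episodes those linked to a
diagnosis within one year of the episode's annual test. AUC is the
Mann–Whitney probability with half tie credit (identical to the trapezoidal
area under the tie-grouped ROC curve), and the paired AUC difference is
tested with the DeLong structural-components estimator using midrank
placements; when both score vectors are identical the difference is exactly
zero and p = 1. The implementation is cross-checked in the test suite
against an all-pairs enumeration, a stratified case/control bootstrap, and
the pROC reference implementation in R.

## Numerical and testing notes

- The flat marginal equals a dense multivariate-normal density to machine
  precision; both flat and change-point marginals are validated against an
  importance-sampled Monte-Carlo integration of the woman baseline (3-SE
  tolerance).
- Degenerate inputs: τ² = 0 collapses to independent noise around μ₀;
  empty grids, non-positive markers, non-monotone times, invalid priors and
  malformed weight vectors all raise precondition errors; zero denominators
  in performance metrics yield flagged undefined estimates, not exceptions.
- All randomness flows through one `numpy` Generator per run; a given seed
  reproduces cohort files byte for byte and episode logs row for row.
- Default problem sizes: the full-scale simulation in the acceptance script
  and test suite uses 20,000 women over 7 annual rounds (~140,000
  episodes, ~60 cancers, about half a minute on one CPU), the scale at
  which the serial-versus-cutoff AUC comparison has adequate power while
  remaining cheap to rerun.

## What the simulator does and does not show

Passing tests demonstrate that the reconstructed algorithm, protocol and
evaluation reproduce the printed arithmetic exactly and the trial's
qualitative conclusion — serial interpretation roughly doubles detection
relative to a fixed 35 U/mL rule at matched conditions — on data generated
under the model's own assumptions. They do not validate the model against
real serial CA-125, which exhibits features the generator omits: age trends,
benign CA-125-raising conditions (endometriosis, cysts, effusions), assay
drift and batch effects, irregular attendance, and heterogeneous case
kinetics beyond a single change point with a constant slope. Two known
quantitative gaps against the trial's printed workload figures, both traceable
to the simple two-component model: the annual repeat-recommendation rate is
~3% of screens versus the trial's 10% (the real algorithm's intermediate
band swept in many more borderline profiles than a well-specified
two-component likelihood ratio does), and surgeries per cancer come out
near 1.5 versus the printed 4.8 (most of the trial's benign surgeries
followed clinician-driven evaluation of scan abnormalities, which the
default disposition returns to screening). Absolute simulated AUCs,
sensitivities and specificities are therefore reconstruction-specific;
the supported claims are the printed-count arithmetic and the qualitative
ordering.
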