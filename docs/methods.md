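# Methods

This note documents the statistical models implemented in `tksig`, the
defaults and their rationale, the numerical choices, and the limits of what
the synthetic-cohort tests establish.

## Synthetic cohort model

The generator produces `n_datasets` studies of `samples_per_dataset`
samples each.  Expression of gene *g* in sample *i* of dataset *d* is

    x_gdi = mu_g + shift_d + scale_d * (signal_gi + eps_gi)

with gene baselines `mu_g ~ N(8, 1.5)` clipped to [4, 12] (log2 scale),
per-dataset affine batch terms, and `eps ~ N(0, 0.3)` measurement noise.
Signals are standard normal except for:

* **receptor genes** (*ESR1*, *PGR*, *ERBB2*): a two-component Gaussian
  mixture tied to the sample's true receptor class (defaults: negative and
  positive component means ±1.6–2.0 apart, SDs ≈ 0.55–0.65, i.e. ≈3 pooled
  SDs of separation, a well-separated but realistic bimodality).  Configs
  whose components are closer than 0.5 × max SD are rejected because
  transcriptional receptor calling is then undefined;
* **planted prognostic genes**: a latent `z_gi ~ N(0,1)` that enters both
  the gene's expression and the relapse hazard.

Disease-free survival follows a Weibull proportional-hazards model,
`S(t | i) = exp(−(t/λ)^k · exp(Σ_g β_g z_gi))`, shape k = 1.2 and scale
λ = 120 months by default (median ≈ 88 months at β = 0 — a realistic
early-TNBC relapse scale with mildly increasing hazard; the exponential
model is the k = 1 special case and the Weibull keeps closed-form checks
available).  Censoring is independent exponential; its rate is solved
numerically so that the expected censored fraction over the realized event
times equals `censoring_rate` (default 0.40).  Overall survival couples to
relapse: 60% of relapsers progress to death after an Exp(12 months) lag,
with follow-up ending at the same censoring time.

Defaults define the study conditions used throughout the tests and the
acceptance script: 4 datasets (3 microarray, 1 RNA-seq, mirroring the
microarray predominance of public breast-cancer compendia) of 410–425
samples; anchor (luminal-A-like, forced ER+/PR+/ERBB2−) fraction 0.20;
non-anchor receptor prevalences chosen so that roughly half the cohort is
triple-negative, giving ≈800 TNBC samples with survival — the scale at
which a 2/3 : 1/3 split leaves a usefully powered validation set.  Five of
the 86 panel genes are planted with |β| = 0.8 per latent unit (three
hazardous, two protective, mirroring the mixed effect directions of the
published 13-gene signature).  All randomness flows from a single seed
through one `numpy` generator; identical configs are byte-identical.

What the generator does **not** emulate: correlated gene modules (immune or
proliferation metagenes), platform-specific mean–variance relationships,
probe-level structure, informative censoring, or clinical covariates linked
to outcome.  Passing tests therefore establish the *internal correctness
and calibration* of the pipeline (type-I error, leakage-freedom, power at
stated effect sizes), not the biological validity of any signature on real
cohorts.

## Harmonization

Probes collapse to genes by maximal per-study variance (missing values
excluded); exact ties resolve to the lexicographically smallest probe id so
runs are deterministic.  Per study, every gene is standardized against the
anchor samples, `z = (x − m_anchor)/s_anchor`; the anchor subgroup is taken
from user/truth labels when available, otherwise from a documented
heuristic (samples called ER-positive and ERBB2-negative).  Fewer than 3
anchors, or a zero anchor SD, falls back to all-sample moments with a
logged warning (a hard-fail switch exists).  Studies pool on their gene
intersection — no imputation.  RNA-seq input is assumed log2-transformed
upstream; values outside [−10, 30] are rejected as implausible.

Receptor calling is per dataset (bimodality is platform-dependent), on the
raw log2 values, with a 2-component Gaussian mixture; the cutpoint is the
posterior-0.5 crossing between the component means, solved in closed form.
A degenerate mixture (weight < 0.05 or separation < 0.5 pooled SD) falls
back to the deepest kernel-density valley between the two largest modes; a
unimodal distribution raises a "not bimodal" error, and a manual cutpoint
can be supplied.  Subtype assignment gives ERBB2 positivity precedence:
ERBB2+ → "ERBB2+"; else ER or PR positive → "ER+/ERBB2−"; else "TN".

## Survival core

Kaplan–Meier uses the product-limit estimator with Greenwood variance and
log-log-transformed 95% bands; the median is the smallest event time with
S(t) ≤ 0.5 (undefined if never reached).  The two-group log-rank statistic
uses the hypergeometric variance at each event time.  Cox models maximize
the Efron-tied partial likelihood by Newton–Raphson with step-halving
(converged when max|score| < 1e-7 or the step < 1e-9, ≤ 50 iterations);
standard errors come from the inverse observed information; confidence
intervals are 95% with the normal quantile 1.959964; AIC = −2 logL + 2k
exactly.  Monotone likelihood (separation) is detected at |β| > 15 and
reported as a flagged, non-converged fit with an effectively infinite HR
rather than an error, since sparse strata of real cohorts produce such
fits.  Wald (not likelihood-ratio) p-values are used throughout.  When all
observed times are distinct — the generic case for continuous simulated
times — every risk-set aggregate is computed from one reverse cumulative
sum over a stacked [1 | X | X_iX_j] array, which is what makes ~10⁵
resampling fits feasible on one core; tied data take a per-event-time Efron
loop.

Screened genes enter the Cox models as continuous z-scored expression (the
dichotomize-first alternative is deliberately not used: it discards
information before selection).  The multivariate-entry rule retains
variables with univariate p < 0.10, in input order.

## Signature discovery

The split is stratified random by platform at (2/3, 1/3), deterministic
given its seed; strata with fewer than two samples go wholly to learning.
The AIC stepwise search is bidirectional and starts from the full screened
model: at each step all single-gene deletions and re-additions are scored
and the largest AIC decrease is applied; ties prefer deletion, then
lexicographic gene order, making the trace deterministic.  Starting from
the full model is the natural choice after a marginal screen (screened
genes begin included and must justify their AIC cost); non-convergent
candidate fits are skipped with a warning.

The risk score is the Cox linear predictor; the classifier cutoff is the
median learning-set score.  The median rule is the simplest deterministic
dichotomization consistent with near-balanced class sizes, and it is frozen
with the coefficients: applying the classifier to validation or external
samples never refits anything.  No stage reads validation outcomes before
the classifier is frozen; a test corrupts validation outcomes post-split
and verifies the signature is unchanged, and a 100-seed null-cohort run
verifies the validation log-rank p is uniform (no selection leakage).

## Resampling null

Each of B random k-subsets of the panel is evaluated by *exactly* the
observed signature's recipe — Cox refit on the learning set, median-cutoff
classification, validation log-rank — because any asymmetry between the
observed and random pipelines would invalidate the comparison.  Replicates
with non-convergent fits or an empty risk class record the conservative
p = 1.  The headline empirical p uses the strict proportion of null
p-values below the observed one; the smoothed (1 + count)/(B + 1) estimate
accompanies it since the strict proportion can be exactly zero.  B defaults
to 10,000 at the CLI (configurable upward); the test suite uses B = 5,000
(planted cohorts) and B = 2,000 (calibration), sizes at which the empirical
p resolves to 2 × 10⁻⁴ and 5 × 10⁻⁴ respectively.

## Differential expression and centroid score

The moderated t-statistic shrinks each gene's pooled two-group variance
(d_g = n₁ + n₂ − 2) toward a prior (d₀, s₀²) estimated by moment-matching
log s²_g with digamma/trigamma identities (trigamma inverted by Newton
iteration); the posterior variance is (d₀s₀² + d_g s²_g)/(d₀ + d_g) and the
statistic is referred to t with d₀ + d_g df (d₀ = ∞ → normal reference;
d₀ = 0 recovers the ordinary pooled t exactly).  logFC is
mean(low-risk) − mean(high-risk), so genes over-expressed in low-risk
samples are positive; the fold-change filter FC > |1.25×| is applied as
|logFC| > log2(1.25) ≈ 0.322 since inputs are log2.  Differential genes
must jointly satisfy p < 0.01, q < 0.01 (Benjamini–Hochberg step-up) and
the fold-change bound.

The centroid score correlates each sample's differential-gene profile with
the per-class median centroids (learning samples only) and reports
r_high − r_low; Pearson correlation is the default (profiles are continuous
z-scores; Spearman is available via a flag).  A positive score predicts the
high-risk class; a Welch t-test compares score distributions between known
classes.  The generic metagene scorer averages (optionally ±1-weighted)
z-scored member-gene rows; published gene-set definitions are inputs (GMT),
not part of the package.

Fisher's exact test for class-by-category tables enumerates all tables with
the observed margins exactly when their count is ≤ 10⁶, otherwise a seeded
Monte-Carlo estimate with 10⁵ fixed-margin draws; continuous variables use
the Welch t-test.

## Problem sizes in the test suite

The statistical suites run at the documented study conditions: screen power
and stepwise recovery over 50 / 25 seeds at ≈800 TNBC samples; pipeline
null calibration over 100 seeds at ≈300 TNBC samples; resampling behaviour
over 20 outer seeds at B = 5,000 (planted) and 50 outer seeds at B = 2,000
(null).  These sizes resolve the tested thresholds (e.g. empirical
p ≤ 0.01 needs B ≥ 100 by construction) while keeping the whole suite
single-core friendly.

## Known limitations

* The anchor-based z-score removes only affine batch effects; nonlinear
  platform distortions (saturation, dropout) are out of scope.
* Receptor calling assumes genuine bimodality per study; cohorts restricted
  to one receptor class will (correctly) fail with "not bimodal" and need a
  manual cutpoint.
* The stepwise search is greedy; it is tested to be no worse than its
  starting AIC and is compared against exhaustive enumeration only at small
  candidate counts.
* No time-varying covariates, stratified baselines, frailty, or competing
  risks in the Cox machinery.
* The shipped 13-gene signature fixture carries the published gene identities
  and univariate effect directions only; its original coefficients would
  require the source patient data and are not re-derivable here.
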