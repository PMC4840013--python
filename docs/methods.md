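# Methods

`sdaeval` audits automated seizure detection algorithms (SDAs) for
neonatal EEG against gold-standard expert annotations. This note describes
the models and procedures it implements, the choices made where the design
was genuinely open, and what the synthetic data does and does not show.

## Event matching and performance metrics

A gold seizure counts as **detected** if at least one detector event
overlaps it — on any channel, anywhere within the seizure's time span, for
any overlap duration (the "spatio-temporal manifold" convention used in
clinical SDA evaluation). A detector event overlapping no gold seizure is
a **false detection** (FD). Every event is classified exactly once, so
matched + false counts always equal the input event count; an event
bridging two gold seizures marks both detected and is not an FD.

Intervals are half-open `[start, end)` in seconds from record start, which
makes adjacency unambiguous: a detection starting exactly at a seizure's
end does not overlap it. A symmetric matching tolerance (seconds added to
each detector event before the overlap test) is exposed and defaults to 0
— the strictest reading of "coincident". No merging of adjacent detector
events is performed; the FD unit is one exported event.

Metrics: the seizure detection rate (SDR) is `100 × detected / total`
gold seizures (undefined, and signalled, with none); the FD rate is
events per hour over the **full** record duration, seizure time included,
since audit FD rates are quoted for whole recordings. Epoch-based
sensitivity/specificity tile the record into non-overlapping epochs
(default 1 s, configurable — the convention is not standardised) and label
an epoch positive if it overlaps any gold (resp. detector) interval.
Pooling across records weights FD/hr by record duration and pools seizure
counts directly.

## Seizure feature schema

Each seizure is scored on 10 criteria: peak amplitude (µV peak-to-trough
at the seizure midpoint), rhythmicity (ordinal 1–3: significant dysrhythmia
→ highly rhythmic), EEG background (1–3: normal → severe abnormality),
discharge morphology at onset and at peak (RDD / RDT / RDA / S,SH /
SH+W,SP+W), duration (s), frequency variability, morphology change
(onset ≠ peak), and channel counts at onset and peak. Amplitude is treated
as µV (not µV²): the measurement procedure is peak-to-trough with a
graticule, so a squared unit would be a typographical artefact.

Frequency variability is the **sample** standard deviation (n−1) of the
discharge frequency at start (first 5 s), peak (mid seizure) and end
(last 5 s); the n−1 denominator matches standard statistical-package
defaults. It is permutation-invariant and scale-equivariant by
construction.

Visual scores are manual-entry inputs. The automated helpers —
`peak_amplitude` (max − min in a mid-seizure window) and
`dominant_frequency` (Welch spectral peak in 0.3–8 Hz, the neonatal
delta–alpha discharge band) — exist for synthetic data and never
substitute expert scores. `dominant_frequency` divides out the power-law
trend of the in-band spectrum before peak picking, so the 1/f tilt of
background EEG is not mistaken for a low-frequency discharge; the peak /
median ratio of the detrended spectrum gates a confidence flag (threshold
4, below which broadband noise typically falls).

## Detectability model: random-intercept logistic GLMM

For seizure *i* of baby *j*:

    logit P(detected_ij | b_j) = β₀ + x_ijᵀβ + b_j,   b_j ~ N(0, σ²)

with seizure features as fixed effects and the baby as the grouping
factor, capturing within-baby correlation of detectability. The marginal
likelihood integrates b_j out by **adaptive Gauss–Hermite quadrature**:
each baby's integrand is re-centred at its posterior mode (1-D Newton,
vectorised across babies) and re-scaled by its curvature before the
Gauss–Hermite rule is applied. 15 nodes are the default (estimates move
by < 1e-4 going to 31 on the test cohorts); one node is the Laplace
approximation. σ is estimated by L-BFGS-B with a `[0, ∞)` bound; a
`fixed_sigma` option fits the model with σ held fixed (σ = 0 is exactly
ordinary logistic regression, which is how the implementation is checked
against an independent oracle — note that on finite samples generated
with σ = 0 the *free* MLE of σ is legitimately sometimes > 0).
Standard errors come from the numerically differentiated observed
information; when σ̂ is on the boundary the Hessian is taken over β only.
The implementation was additionally cross-checked against lme4's `glmer`
(nAGQ = 15) on a frozen synthetic dataset: coefficients, σ̂ and the
log-likelihood agree to ~1e-5.

Inference and reporting: Wald z per coefficient; odds ratios
`exp(β̂ ± 1.96·SE)`; multi-level categorical terms get a single
likelihood-ratio block p-value. Reference levels are fixed: significant
dysrhythmia (rhythmicity), normal (background), RDD (morphology).

**Model building**, run independently per sensitivity threshold:

1. *Univariate screen* — one single-feature GLMM per feature; p < 0.05
   marks a candidate. Fit failures (e.g. separation) are annotated per
   feature, not fatal.
2. *Collinearity filter* — features visited in decreasing univariate AUC;
   a candidate is dropped when |Spearman ρ| > 0.8 (configurable) with an
   already-retained feature, so the higher-AUC member of a collinear pair
   survives. Categorical columns enter through sorted level codes.
3. *Backward stepwise deletion* — drop the term with the largest
   p ≥ 0.05 (Wald for single columns, LR block for categoricals), refit,
   repeat. If everything is removed the intercept-only model is returned
   with a warning. Whether the original audits used Wald or LR p-values
   in deletion is not documented; LR for blocks is the conservative
   choice here.

Model AUC uses the **fixed-effects-only** (population-level) linear
predictor — the honest default for a new baby; a conditional
(posterior-mode random-effect) variant is available behind a flag. AUC
CIs use the DeLong variance estimator; correlated AUCs (multivariate
model vs its best single feature, scored on the same seizures) are
compared with the DeLong paired test. The AUC estimator is identical to
brute-force concordance counting (ties = ½), which the tests verify
exactly. Group FD-rate comparisons (seizure vs seizure-free babies) use
the Mann–Whitney U test: exact p for ≤ 10 per group without ties (the
canonical 10-vs-10 design), normal approximation with tie correction
otherwise. No multiple-testing correction is applied, matching audit
practice; a flag can add it.

## False-detection taxonomy

Categories are a closed vocabulary: respiration, ECG/pulse,
chewing/sucking, bad/loose electrode, movement/handling (patting,
stroking), electronic equipment, sweat, unclassified artefact, and
no-artefact; no-artefact events additionally carry a background
description (normal / highly rhythmic / sharp waves / low amplitude).
Unknown labels are rejected, not coerced. Categorisation is an expert
label imported with the events — no automated artefact classifier is in
scope.

Reports follow the audit-table conventions: category percentages are of
all FDs at that threshold; the no-artefact breakdown is a percentage of
the no-artefact count. Rendered tables round to 1 decimal; machine
output keeps full precision. Per-patient concentration reports the
patient with the maximal category count and its share; threshold
drop-off reports count(t)/count(t_min) per category, flagging zero
baselines.

The bundled worked-example tables (`sdaeval.audit_tables`) carry the
published aggregate counts of a two-centre clinical audit of an SDA over
20 term neonates and 1262.9 h of EEG; the expander functions turn counts
into records so the aggregation code reproduces the published shares by
explicit computation. Two internal inconsistencies of the published
tables are preserved as published and reported by exact arithmetic
(a 47.9% share whose own counts give 47.0%; a sweat category total of
160 in the table vs 149 in the concentration example, whose stated
denominator is used for that example).

## Synthetic cohorts

`generate_cohort` plants a detectability model with known ground truth.
Each seizure draws features from distributions chosen to look like a
neonatal audit cohort: lognormal durations (median ≈ 55 s, log-SD 0.9),
lognormal peak amplitudes (median ≈ 100 µV), rhythmicity levels
(0.25/0.40/0.35), onset morphology dominated by rhythmic delta with a
transition matrix that frequently evolves RDD into sharp-and-slow-wave
complexes at peak, 1–8 channels with the field widening onset → peak, and
frequency variability computed (by the schema's own formula) from three
jittered per-seizure frequency measurements. Default planted effects sit
at the odds-ratio scale typical of such audits: OR 1.02 per second and
per µV, 1.4 per channel at peak, 2.5/5.0 for rhythmicity levels, 2.3 for
morphology change; default cohort 20 babies × 20 seizures,
random-intercept SD 1.

The latent detector score is drawn **once** per seizure:

    s_ij = expit(β₀ + x_ijᵀβ + b_j + ε_ij),  ε_ij ~ Logistic(0, 1)

and `detected_at(t) = (s_ij ≥ t)`. Because a single draw is compared to
every threshold, flags are automatically nested across the grid; and
because ε is standard-logistic, P(detected at t) is *exactly* the planted
random-intercept logistic model with slopes β and intercept β₀ − logit t
— so the GLMM run at any threshold estimates the same planted
coefficients. (Thresholding a noise-free expit(β₀+xβ+b) instead would
make the outcome deterministic in (x, b) and separate completely.) The
intercept is centred by default so the median latent score is 0.5,
keeping outcomes non-degenerate at all three clinical thresholds.

`generate_fd_stream` plants patient-clustered artefact streams: per
category, a Poisson cohort count (default rates reproduce an ~800-FD /
1260-h audit mix), patient assignment by Dirichlet(0.3) weights (small
concentration → a single patient dominating a category, as observed for
respiration and sweat), and one latent uniform level per event compared
against a non-increasing per-category survival profile — so
higher-threshold lists are subsets, and respiration (survival 1/0.9/0.8)
falls gently while sweat (1/0.61/0.09) collapses.

## Toy EEG and the reference detector

`synthesize_eeg` places events on a pink-noise (1/f, 25 µV RMS, 256 Hz)
background over an 8-channel neonatal bipolar montage. Seizures are
amplitude-enveloped frequency-modulated oscillations: per-second frequency
jitter SD is tied to the rhythmicity score (0.50/0.25/0.06 Hz for levels
1/2/3) and, with the evolution flag, harmonics ramp in towards the peak
(near-sinusoidal delta → spike-and-slow-wave). Artefacts: respiration — a
sustained, highly rhythmic ~1 Hz sinusoid; sweat — an intermittent,
semi-rhythmic ~0.35 Hz drift; pulse — an impulse train at cardiac rate;
movement — sparse high-amplitude broadband bursts. These are caricatures
built to exercise the pipeline, **not** physiological EEG: passing tests
demonstrate that the analysis machinery behaves correctly on data with
known ground truth, not that any detector performs clinically.

The reference detector mirrors the canonical SDA architecture with a
fixed, documented linear score instead of a trained classifier: per
channel, 8-s epochs at 50% overlap → feature vector (log relative RMS,
1 − normalized spectral entropy, 0.5–4 Hz power fraction, log spectral
peak prominence) → linear score → sigmoid → 3-epoch moving average; the
cross-channel trace is the per-epoch maximum, and events are maximal runs
at or above threshold with the peak channel attached. Epochs with RMS
above 400 µV are pre-masked (simple high-energy artefact removal). The
weights (2.0, 10.0, 1.5, 0.5, bias −10.3) were set once from the feature
distributions of the generator's background vs rhythmic high-amplitude
activity so that pink noise scores well below zero; they are not trained
and claim no clinical performance.

`adaptive_baseline` implements the local-preceding-baseline correction
qualitatively described for improved SDA versions: each probability is
replaced by `(p − m)/(1 − m)` clipped to [0, 1], where m is the median of
the trailing window (default 30 min — no window is documented, so it is a
parameter). A prolonged artefact-elevated baseline is suppressed while a
transient excursion above the local baseline survives (rescaled so a
full-scale excursion still reaches 1). Traces shorter than the window use
the available history with a warning. The published description is
qualitative; this subtract-trailing-median form is one admissible reading
and is isolated in a single function for replacement.

## Numerical choices and problem sizes

Quadrature: 15 adaptive GH nodes; Newton mode search to 1e-10;
separation is detected pre-fit (disjoint covariate ranges across outcome
classes) and post-fit (|β̂| > 15), both raising a named error. Ties in
AUC count ½; a constant score raises rather than returning a meaningless
AUC. Default simulation sizes — 20 babies × 20 seizures for cohorts, 200
replicates for coverage checks, 1000 random instances for the matching
oracle — keep the full validation suite around half a minute while
leaving Monte-Carlo error well inside the asserted bounds (3 SE bands;
binomial bounds on rejection counts).

## Known limitations

- The GLMM supports a single random intercept (baby); no random slopes or
  crossed/nested factors.
- The synthetic EEG has no sleep cycling, burst suppression, inter-ictal
  discharges or channel-specific artefact topography; detector results on
  it say nothing about clinical sensitivity.
- Expert visual scores (rhythmicity, morphology, background) cannot be
  computed from EEG here; only their data model and validation are
  provided.
- The reference detector's score is fixed, so its absolute SDR/FD rates
  are properties of the generator, not of any clinical system.
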