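# Methods

`cogvasc` re-implements, as a tested pipeline, a cross-sectional analysis
of mild cognitive impairment (MCI) versus cognitively normal (CN) older
adults built from four measurement streams: task-evoked neurovascular
coupling (NVC) from fNIRS, graph-theoretical functional connectivity
(FC), behavioral working-memory performance (d′), and cerebrovascular
endothelial extracellular vesicles (CEEVs) from small-particle flow
cytometry.  Because no raw data from such studies are public, the
package ships a first-class synthetic-data generator whose outputs carry
ground truth, so every stage can be validated by parameter recovery.

## fNIRS forward model and preprocessing

**Acquisition model.** 48 source–detector channels over the frontal
cortex (10-20 anchored; only the left-DLPFC triple F3-F5, F3-F1, F3-FC3
is anatomically load-bearing), 3 cm separations, wavelengths 760/850 nm,
sampling 3.9 Hz.  Relative chromophore changes ΔHbO/ΔHbR (μM) map to
optical-density changes through the modified Beer–Lambert law
ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·d·DPF(λ), with molar extinction
coefficients from the standard compiled hemoglobin spectra
(760 nm: 1486.59/3843.71, 850 nm: 2526.39/1798.64 cm⁻¹M⁻¹) and a
differential pathlength factor of 6.0 at both wavelengths (configurable;
no instrument-specific value was available).  Intensities are
I = I₀·10^(−ΔOD); the analysis inverts exactly these relations, so
noiseless simulations are recovered to machine precision (validated to
<10⁻⁶ relative error).

**Quality screen.** The scalp-coupling score per channel is the Pearson
correlation between the two wavelengths' cardiac-band (0.5–2.5 Hz,
capped below Nyquist) signals; a pulsatile component visible at both
wavelengths indicates optode contact.  A channel is poor below 0.75
(configurable; the rule's consequences, not its metric, were specified,
so the metric and cut are package choices).  A subject is excluded when
>80 % of montage channels are poor or any LDLPFC channel is poor.  The
80 % rule is evaluated over all 48 montage channels.

**NVC branch.** OD → motion handling → MBLL → DCT high-pass (0.009 Hz)
→ AR prewhitening (jointly with the design) → OLS.  Motion handling
re-levels baseline steps (flanking medians; spike-resistant) and
replaces |z|>5 rolling-median outliers with the local baseline.  The DCT
projection removes every basis vector below the cutoff, including the
constant, and the identical projection is applied to the design matrix —
otherwise betas are attenuated by a block-position-dependent factor.
Prewhitening fits AR(p), p ≤ 4 chosen by AIC via one Levinson–Durbin
pass on the OLS residuals, and filters data and design with
(1 − φ₁B − … − φ_pB^p); a nonstationary fit falls back to AR(1).  This
is AR-prewhitened OLS; no robust (IRLS) reweighting is applied.

**FC branch.** OD → zero-phase 5th-order Butterworth band-pass
(0.0045–0.4 Hz) → MBLL → correlation-based signal improvement (CBSI:
with α = SD(HbO)/SD(HbR), HbO′ = (HbO − α·HbR)/2, HbR′ = −HbO′/α, which
enforces corr = −1 and cancels same-sign motion) → HbT = HbO′ + HbR′.
Zero-phase filtering is used because the correlation analyses are
phase-sensitive, and the band-pass is applied circularly in the
frequency domain with the forward-backward gain |H(f)|²: a recursive
forward-backward pass leaves edge transients longer than the low
corner's period, which makes the filter response position-dependent and
biases windowed correlations against their surrogate nulls (measured
null SD 0.26 at the first block vs 0.14 mid-session with the recursive
form; uniform 0.14 with the circular form).  The two branches never
share filters; provenance flags on the series assert this.

## First- and second-level GLM

One regressor per n-back condition (0b_1, 0b_2, 1b, 2b): a 72-s boxcar
convolved with a canonical double-gamma HRF (response peak 6 s,
undershoot peak 16 s, undershoot ratio 1/6; peak-normalized so β is the
response amplitude in μM).  The same kernel drives the simulator, so
simulation and analysis cannot drift apart.

The second level fits, per channel, cell means for every group ×
condition combination (no intercept) with a subject random intercept,
and evaluates t-contrasts: between groups on a condition (unpaired),
or within group across conditions (paired; the subject intercept
cancels).  For balanced inputs the model is solved in closed form via
split-plot ANOVA mean squares — identical to REML on balanced data (a
unit test checks agreement with an iterative mixed-model fit) — with
Satterthwaite degrees of freedom; unbalanced inputs fall back to the
iterative fit.  The cognitive-load contrast is (2b + 1b) − 2×0b_2
(sum-zero); the second 0-back is the baseline by default, configurable.
Channel families are corrected by Benjamini–Hochberg FDR; a channel map
is significant at q < 0.05.  HbO is the primary chromophore; HbR maps
are computed but secondary.  Realized FDR under a null group contrast
was measured at ≈0.056 over 500 simulated families (bound 0.07).

## Connectivity graphs

Pearson correlations of HbT over each 72-s block window (≈281 samples)
for all channel pairs.  Edges are kept only when positive and
significant against a surrogate null: random circular time-shifts of one
channel, which preserve autocorrelation and destroy cross-correlation.
Shifts are drawn over the whole session and the block window extracted,
because wrapping the block itself narrows the null (measured retention
0.078 instead of ≈0.05 under independence).  One-sided
p = (1 + #{r_surr ≥ r_obs})/(n_surr + 1), default n_surr = 200 (≥19
required at α = 0.05); a parametric t-test alternative is selectable.

Metrics on the thresholded matrix r*: binary degree D_i and its
normalized global mean D̄ = mean_i D_i/(N−1); node strength
ʷD_i = Σ_j r*_ij normalized by (N−1) × the maximum edge weight observed
in that subject-block graph (this realizes "relative to the maximum
connection strength" and guarantees [0, 1]; dividing by (N−1) alone is
available as a config switch).  LDLPFC variants average the three LDLPFC
channels' normalized values; task-averaged variants average over the
four blocks (available-mean when a block is missing).  Matrices are
Fisher-averaged (atanh before the mean, tanh back); scalar metrics are
averaged in natural units.  All metrics are checked exhaustively against
a brute-force enumeration for small graphs.

## Behavior

d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate).  Rates of exactly 0 or 1
are corrected by the 1/(2N) rule before the quantile transform
(log-linear alternative available).  Mean RT is taken over correct
responses only — responded targets; correct rejections carry no response
and contribute no RT.

## EV cytometry

Three logical fluorescence channels: pooled endothelial
(CD31/CD144/CD105, one fluorophore), pooled lymphocyte/platelet
exclusion (CD3/CD41), and MAL (CNS-endothelium marker).  Positivity
gates are the 99.9th percentile of the matching fluorescence-minus-one
control (percentile configurable), never derived from the stained
sample.  Gating is sequential: exclude lymph/platelet-positives; call
the rest endothelial by the pooled channel; split endothelial by MAL
into CEEV (MAL⁺) and EEV-only (MAL⁻); MAL⁺ non-endothelial events are a
separate population.  CEEV ratio = 100 × CEEV/(CEEV + EEV-only);
concentrations are events per μL of acquired volume (1.5 μL/min × 120 s
= 3 μL) times the dilution factor.  CEEV diameters are binned at
[0,180), [180,600), [600,1000), [1000,∞) nm.  Aliquot replicates are
averaged arithmetically.  Spillover compensation is not modeled; the
synthetic channels are conditionally independent given the class.

## Statistics layer

Mann–Whitney U (exact for ≤8 per group without ties), mixed two-way
ANOVA (between = group, within = task; no sphericity correction by
default) with Bonferroni-adjusted group comparisons per task level,
Spearman and Fisher's exact tests, and BH-FDR (step-up, monotone
q-values, rejection at q < 0.05 strict).  Cohen's d from summary
statistics defaults to the rms-SD variant |m₁−m₂|/√((s₁²+s₂²)/2), which
reproduces the published LDLPFC degree effect size (0.6047) exactly; the
pooled variant is available.  ROUT outlier removal is implemented for
group vectors, where the robust regression degenerates to a constant
fit: location = median, scale = 68.27th percentile of |residuals| with
an N/(N−K) small-sample correction; residual t statistics are screened
by a step-up FDR test at rate Q (0.1 % → Q = 0.001).  Measured
false-flag rate on clean Normal samples (n = 20): 0 of 10,000 points.

## Classification protocol

Features per subject: task-averaged LDLPFC HbO β, CEEV ratio (%), the
four task-averaged connectivity metrics (ʷD_LDP, D_LDP, D̄, ʷD̄), age,
sex, hypertension, and prior depression.  Leave-one-out
cross-validation; inside every training fold the numeric features are
standardized and sex one-hot encoded (refit per fold, so no information
leaks from the held-out subject), a random forest is fitted, and Gini
importances are recorded; the per-feature arithmetic mean across folds
ranks the features.  The top k = 3 are kept (ties broken by fixed
feature order).  The final forest uses 500 trees and is evaluated on a
stratified 80/20 split (accuracy, support-weighted precision and recall,
F1 = harmonic mean of that precision/recall pair) and over repeated
stratified splits with distinct derived seeds (default 100).  Stratified
splits avoid single-class test sets at n = 34.  Forest defaults beyond
tree count follow the library, pinned by the seed.

## Synthetic cohorts: what is emulated, and what is not

Ground-truth ΔHbO per channel is the sum of (i) the task response —
condition regressor × a group/region amplitude plus a subject-level
offset (SD 0.10 μM in LDLPFC), (ii) a shared band-limited fluctuation
carrying the FC structure, (iii) systemic physiology, and (iv) AR(1)
noise (SD 0.03 μM, φ = 0.4); ΔHbR is −1/3 of the neural-vascular part
plus independent noise, while systemic components enter both
chromophores with the same sign (blood-volume driven) — necessary for a
meaningful two-wavelength coupling score.  Motion spikes/steps are off
by default and configurable.

FC structure uses a single latent factor: channel i mixes the factor
with weight √w_i, so corr(i, j) = √(w_i w_j).  Default weights: LDLPFC
0.75 (CN) / 0.55 (MCI), background 0.40 (both), and a homotopic
right-DLPFC reference pair at 0.90 (both) that anchors each graph's
maximum edge weight so the strength normalization is stable across
groups; subject-level jitter SD 0.05.  The background level is chosen so
edge retention is near-saturated in both groups: the binary degree
metrics then carry little group information while strength carries
much, reproducing the study's strength-over-degree importance ordering.
The fluctuation bandwidth equals the FC analysis band (≤0.4 Hz).

Amplitudes (μM, at the regressor peak): CN LDLPFC 0.30/0.30/0.45/0.55
across 0b_1/0b_2/1b/2b; MCI LDLPFC 0.18/0.18/0.22/0.25; background 0.20
everywhere.  These encode the reported effect *directions* (reduced MCI
LDLPFC response, absent load response) at magnitudes detectable at
desk-scale cohort sizes; no quantitative μM effect size was available to
copy.  Behavioral parameters plant intact 0-back performance and
impaired MCI 2-back performance (hit 0.65 vs 0.85, FA 0.12 vs 0.05, RT
780 vs 640 ms).  CEEV fractions are Normal per subject: CN 0.055 ±
0.025, MCI 0.13 ± 0.05 (truncated to (0.005, 0.6)), matching the
reported group medians (≈5.5 % vs ≈12 %).  Demographics follow the
published cohort table (ages ≈71 ± 7 truncated at 50; sex, hypertension
and prior-depression rates per group); the fluid-cognition composite is
drawn from the reported group distributions.  The MCI Fazekas grade
(0–3) is generated from the subject's latent CEEV propensity through a
noisy rounding (association ρ ≈ 0.7), reproducing a Spearman association
without claiming a mechanism.

EV event tables mix six classes (debris 0.30, platelet 0.18, lymphocyte
0.12, endothelial 0.25 split by the subject's CEEV fraction, MAL⁺-other
0.15) with log₁₀ fluorescence Normal(2.0, 0.25) for negatives and
Normal(3.4, 0.25) for positives (arbitrary units — gates come from FMO
percentiles, so absolute scale is immaterial), and log-normal diameters
(median 160 nm, σ_log 0.6, clipped to the 80–1300 nm instrument range).
Default 50,000 events per aliquot, two aliquots, 200× dilution.

Not emulated: photon transport and partial-volume optics, letter-stream
psychology beyond Bernoulli responses, fluorescence spillover,
cytometer electronics, and any real spatial structure beyond the
region labels.  Passing tests therefore demonstrate that the analysis
chain is correct and calibrated under the stated generative model, not
that it would detect effects of the published magnitude in real
recordings.

## Problem sizes in the validation suites

The test and acceptance runs use desk-scale sizes chosen to keep full
validation runnable on one CPU: cohorts of 17+17 (the classification
sample size), 10,000–50,000 EV events per aliquot, 100–200 surrogates
per edge, 300–500 Monte-Carlo replicates per calibration claim, 50
cohorts for the feature-selection rate, and 20–25 repeated splits per
cohort for accuracy summaries.  Each reported quantity states its
problem size.

## Known limitations

* The second-level closed form assumes balance; heavily unbalanced
  designs take the slower iterative path.
* ROUT is a re-derivation for constant fits from the published
  description; it is not numerically identical to the original
  nonlinear-regression implementation.
* The montage's non-LDLPFC channel labels are a documented convention;
  analyses depend only on labels and the LDLPFC set.
* SNIRF support covers the subset of the format the package writes
  (single data block, two wavelengths, intensity data).
* FCS binary ingestion is not implemented; cytometry event tables enter
  as CSV.
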