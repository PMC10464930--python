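# Methods

`erpiat` implements the analysis chain of a two-group implicit-suicidality
ERP study — behavioral D scoring of a Death/Suicide Implicit Association
Test (DS-IAT), per-subject condition-contrast ERPs, a mass-univariate
robust ANCOVA over the channel × time grid, spatiotemporal cluster-mass
permutation correction, and exploratory ROC classification — together with
a synthetic-data generator whose injected effects make every stage testable
against known ground truth. This note records the models, the defaults and
why they were chosen, and the places where a genuine design decision had to
be made.

## Behavioral model and D scoring

The DS-IAT has seven blocks: three single-categorization blocks and two
pairs of combined blocks in which "death"+"self" (death-congruent) or
"life"+"self" (life-congruent) share a response key; each pairing spans a
practice and a test block, counterbalanced in order across participants.
The D score is the standardized IAT effect

    D = ( mean RT(life-congruent) − mean RT(death-congruent) ) / SD_incl

oriented so that faster death-congruent responding gives D > 0 (a stronger
implicit death–self association). `compute_d_score` applies the improved
algorithm in this order:

1. drop latencies > 10,000 ms;
2. replace each error trial's latency with its block's mean correct
   latency + 600 ms (the built-in error penalty; a drop-errors policy is
   available behind `ScoringPolicy(error_policy="drop")`);
3. recode latencies < 300 ms to 300 and > 3000 ms to 3000 (recoding, not
   dropping — the bounds can be disabled, which restores exact
   location-scale invariance of D);
4. pool practice + test blocks per condition and use one inclusive SD over
   all retained paired-block latencies (`combine="pooled"`, the default);
   `combine="averaged"` instead averages the practice-pair and test-pair D
   values, each with its own inclusive SD.

Degenerate inputs: a condition left empty after filtering makes the
participant unscorable (flagged and excluded, never silently scored);
zero pooled variance with zero mean difference yields D = 0.

Group differences in D are tested with an ANCOVA `d ~ group + age +
gender` (group 0 = control, 1 = patient, so effects read as patient −
control; gender enters as a binary indicator — a documented
simplification). Within the patient group, C-SSRS ideation-intensity
subscales are compared between positive-D and negative-D participants
adjusting for depression severity (CDRS-R total).

## Synthetic data generator

Reaction times are ex-Gaussian (Gaussian μ = 500 ms, σ = 80 ms convolved
with exponential τ = 150 ms — plausible adolescent IAT latencies). Each
participant carries a latent congruency effect `e` added to their
life-congruent latencies, so `e` maps directly onto the expected D via the
latency scale √(σ² + τ²) ≈ 170 ms. Defaults: control latent mean −60 ms,
patient = control + 45 ms, between-subject SD 40 ms. These place the two
group D means near −0.35 and −0.09 — both groups life-leaning, the patient
group closer to zero — which is the configuration the package's behavioral
tests exercise. Error trials occur at 7%; inter-stimulus intervals jitter
uniformly in 1300–1500 ms; paired blocks hold 40 trials by default (single
blocks half that), all configurable.

Epochs are sums of component templates — Gaussian in time, Gaussian on the
scalp around a centroid sensor — for N100 (peak 200 ms, −5 µV,
parieto-occipital), P200 (230 ms, +4 µV, left frontal) and LPP (700 ms,
+3 µV, centro-parietal, broad). Templates are zeroed before stimulus onset
so the baseline carries noise only. The condition contrast at the chosen
effect component is δ = β_group·g + β_D·d + β_age·age_c, added as ±δ/2 to
death/life trials, so avg(death) − avg(life) recovers δ exactly at the
template peak. Injection uses the participant's *latent* D; regressing on
the behaviorally estimated D instead attenuates the slope by the usual
errors-in-covariates factor, which is why the recovery experiments regress
on the latent value and the estimated-D path is covered separately by the
rank-correlation monotonicity property (ρ > 0.9).

Noise is AR(1) in time (coefficient 0.95, scaled to a stationary SD of
5 µV, 100-sample burn-in) mixed across sensors with a row-normalized
Gaussian kernel (SD 30 mm) — enough temporal and spatial correlation to
make cluster calibration meaningful, while remaining simple. The generator
does not model cortical sources, eye/muscle artifacts, or stimulus
semantics; passing tests therefore demonstrate the statistical machinery's
calibration under a known, well-behaved generative model, not robustness
to every pathology of real recordings.

Sensor layouts are deterministic Fibonacci spirals on the upper hemisphere
(radius 90 mm, labels `E1…En`), written and read as plain `label x y z`
files. Randomness derives from one master seed via per-(stage,
participant) `SeedSequence` spawn keys, so participant k is reproducible in
isolation and identical configs give bit-identical outputs.

## Preprocessing

Epoch window −200…+1000 ms with baseline −200…0 ms by default (the LPP
extends late, motivating coverage beyond 900 ms). Trial-by-trial artifact
handling: per trial, channels exceeding 100 µV peak-to-peak are
interpolated from the good channels with inverse-squared-distance weights
(a convex combination); trials with more than 10 bad channels are dropped;
channels bad in over 30% of trials are interpolated globally; every action
is logged. Participants with fewer than 10 retained epochs in either
condition are excluded (the boundary is inclusive: 10 passes). No offline
band-pass is applied by default. The subject contrast is the elementwise
difference of condition trial-means, optionally boxcar-decimated (default
factor 4, i.e. 1000 → 250 Hz) identically in both conditions to keep the
statistical grid tractable; latencies are always reported in original ms.

## Group-level model

The design has intercept, group (0/1), D score and age in months, the
continuous covariates mean-centered (verified to ≤1e-10); rank deficiency
is reported with the offending columns. This is the two-stage
summary-statistic reading of a hierarchical model: level 1 is the
within-subject trial averaging, level 2 the between-subject regression at
every channel × time cell.

Two fitting paths share one vectorized core: closed-form OLS with partial
F = t² per regressor, and a robust bisquare IRLS (Tukey biweight, tuning
4.685, MAD scale, ≤50 iterations, tolerance 1e-8) with an approximate
robust Wald F from the weighted information matrix. On outlier-free data
the robust path coincides with OLS (and is cross-checked against
statsmodels' RLM in the tests); cells where IRLS fails to converge fall
back to OLS and are flagged rather than failing the field.

## Cluster-mass permutation

Sensor adjacency is a distance-threshold graph (default 40 mm on the
64-channel layout; 65 mm on the sparse 16-channel reduced grid). Cells
with F above the cluster-forming threshold (per-cell p < .05 converted to
an F quantile at the model's dfs) are joined when they share a channel at
adjacent timepoints or are neighboring channels at the same timepoint — no
diagonal moves. An optional channel partition restricts clusters to
regions. Cluster mass is the summed F.

The null is Freedman–Lane: fit the reduced model without the tested
regressor, permute its residuals across participants, add them back to the
reduced fit, refit the full model, and record the maximum cluster mass per
permutation (default 1000 permutations). Corrected p = (1 + #{null ≥
mass}) / (1 + n_permutations): the add-one estimator floors p at 1/(n+1)
and ties count as exceedances (conservative). Both the observed and the
permuted F fields use the OLS statistic inside the permutation test — the
two must be the same statistic for exchangeability, and an IRLS refit per
cell per permutation buys little for what it costs; the robust field
remains the estimation output. This choice, the no-diagonal connectivity,
and the whole-montage default region are declared package decisions.

## Classification and power

Cluster features are the per-participant mean contrast over a cluster's
cells. Group classification is a logistic model on standardized
predictors, scored by trapezoidal ROC AUC; with stratified k-fold CV,
out-of-fold scores pool into one curve. Complete separation (detected from
the fitted scores) switches to a small fixed ridge penalty and flags the
result — the exploratory label is deliberate. AUC equals the
concordant-pair (Mann–Whitney) estimate on untied data, which the tests
assert.

ANCOVA power uses the noncentral F: df1 = groups − 1, df2 = N − groups −
covariates, λ = f²·N, power = P(F′ > F_crit). At f = 0 this equals α
exactly. The reference design (27/group, f = 0.5, α = .05, 2 covariates)
gives 0.950, comfortably above the 80% design target, and matches a
100k-replicate simulated ANCOVA within Monte-Carlo error.

## Problem sizes used in the validation experiments

The replicate-study experiments (`erpiat.experiments`) run the full chain
on a reduced grid chosen so hundreds of replicates complete in minutes:
16 channels, 50 timepoints (50 Hz over −200…800 ms), 20/group, 12 epochs
per condition, 800 permutations for null calibration (200 studies) and 200
permutations for localization (100 high-SNR replicates with β_D = 6 µV/D,
noise 3 µV). Recovery uses 100 replicates at β_D = 0.5 µV/D with 30/group.
Directional behavior checks use 200 replicates of the full-size behavioral
simulation with a 150 ms latent group shift.

## Known limitations

- The generator's spatial model (Gaussian spread on a hemisphere) has no
  forward head model; topographies are caricatures.
- Gender is a binary covariate in the ANCOVAs.
- The robust Wald F uses a pragmatic weighted-information variance, not a
  full sandwich estimator; its p-values are approximate and the
  permutation path is the inferential authority.
- Regressing on estimated (rather than latent) D attenuates ERP–D slopes;
  real studies face the same measurement-error caveat.
- EDF/BDF export is not provided; the HDF5 container plus CSV/montage text
  files are the interchange formats.
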