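# Methods

`wpaflow` implements a single-event platelet aggregation analysis for
imaging flow cytometry (IFC): synthetic event streams and cohorts in, gated
and classified events out, scored by the weighted platelet aggregation (WPA)
statistic, quality-filtered in two stages, and summarised with cohort-level
statistics. This note documents the models, the defaults and why they were
chosen, the numerical choices, and what the synthetic data does and does not
show about real measurements.

## The measurement being emulated

In IFC of antibody-labelled whole blood, every acquired object is a small
multi-channel image (brightfield, CD42b, CD62P). Roughly 99 % of objects
are CD42b-negative erythrocytes; acquisition-side conditional gating on
CD42b-positive, camera-focused events keeps file sizes manageable and
retains ~10^4 platelet complexes per measurement. Each retained complex is
a singlet, doublet, triplet or multiplet (≥ 4 platelets). A typical
unstimulated measurement contains about 8400 singlets, 200 doublets, 10
triplets and 0–1 multiplets; ADP stimulation multiplies doublets ≈ 2.5×,
triplets ≈ 7× and multiplets ≈ 5× while depleting singlets by the platelets
consumed.

## WPA

For per-class event counts `m1..m4` with total `N`:

    WPA = ((1·m1 + 2·m2 + 3·m3 + 4·m4) / N − 1) × 100   [%]

The baseline subtraction anchors pure-singlet measurements at 0 %; a
measurement of exclusively multiplets attains 300 %. The multiplet weight
is fixed at 4 whatever the true aggregate size — that is what bounds the
score, since the four-class output cannot distinguish larger aggregates.
The denominator is the number of gated platelet *events* (complexes), not
of constituent platelets. The reference unstimulated composition
(8400, 200, 10, 0) scores 2.56 %. Internally WPA is computed at full
precision; reports round to 0.1 percentage points.

## Synthetic event images

- Geometry: 48×48 px per channel at 0.33 µm/px; platelet diameters uniform
  in 2–3 µm. An aggregate is built by attaching each new disk tangent to a
  uniformly chosen existing member at a random angle with ±10 % jitter on
  the center distance; placements that would interpenetrate a non-anchor
  member by more than 15 % of the radius sum are rejected and redrawn
  (platelets deform rather than overlap). Multiplet member counts are drawn
  uniformly from {4, 5, 6}; the ground-truth class is `min(n, 4)`.
- Optics/noise: isotropic Gaussian blur (σ = 1 px; out-of-focus events use
  3×), Poisson shot noise on signal, additive Gaussian read noise (σ = 3
  counts). Brightfield is an absorbing background (level 500, absorption
  0.35); fluorescence amplitudes scale with the event's simulated MFIs.
- Background objects: erythrocytes as large CD42b-negative annuli (central
  pallor as a simple dimple — no attempt at true biconcavity),
  platelet–erythrocyte coincidences (a platelet tangent to an erythrocyte,
  flagged `contains_erythrocyte`), and dim debris.

## Synthetic cohorts

- Counts: per-donor class probabilities are a Dirichlet perturbation of the
  configured class means (`inter_donor_dispersion` is the single spread
  parameter); per-measurement counts are multinomial draws. Dispersion 0 is
  the fully deterministic degenerate case — counts equal the configured
  means (largest-remainder rounding) — used for exact-arithmetic tests.
- ADP: class means 2–4 are multiplied by (2.5, 7, 5); the singlet mean
  drops by `2·Δµ2 + 3·Δµ3 + 4·Δµ4`. Because singlets are consumed, the
  recorded complex total of an ADP measurement shrinks by the same amount
  (`events_per_measurement` anchors the baseline condition). A depletion
  exceeding the available singlets is a parameterisation error.
- Donors: 96 donors by default, 61 male / 35 female assigned
  deterministically; ages from a scaled Beta(2, b) with b solved so the
  median hits 39 years on [18, 70]. Acquisition dates batch up to 12 donors
  per day. Two technical replicates per condition.
- MFIs: per-event CD42b and CD62P are log-normal (CD42b median 5000 a.u.,
  σ_log 0.4; CD62P median 200 a.u., σ_log 0.5); ADP adds +1.0 to the CD62P
  log-location only. An optional linear attenuation of CD62P with aggregate
  class (epitope masking in basal aggregates) exists but is off by default.
- Whole-blood background: `whole_blood_platelet_fraction = 0.01` (the 99 %
  erythrocyte excess). Cohort tables store only the platelet-complex stream
  plus contaminants — exactly what the instrument's conditional gate would
  store; `simulate_whole_blood_stream` produces the full ungated stream for
  gate-rate experiments. The coincidence fraction (platelet+erythrocyte
  images among recorded events) is a free parameter, default 1 %, since no
  reference magnitude exists for it.
- Planted effects for recovery experiments: a male-only per-year fractional
  increase of the aggregate means (µ2..µ4), and an age slope on total
  recorded events. Both default to 0.
- Seeding: one master seed; every donor/measurement/stage derives its
  stream through fixed `SeedSequence` keys, so outputs do not depend on
  iteration order.

## Gating

Events are kept when CD42b MFI ≥ threshold AND focus ≥ threshold AND (by
default) not flagged as a coincidence; the report partitions every input
event into exactly one bin, in the test order CD42b → focus → coincidence.
The `auto` CD42b threshold is an Otsu split on log-MFI (valid only on
bimodal whole-blood streams — on a pre-gated platelet-only stream it would
split the platelet mode itself, so the pipeline default is a fixed 300 a.u.,
between the erythrocyte (~30) and platelet (~5000) medians). The `auto`
focus threshold is the 5th percentile of focus scores among CD42b-positive
events; being a quantile it is *not* idempotent — re-gating with it cuts a
fresh 5 % — so the resolved numeric thresholds are recorded in the report
and should be reused for reproducible re-gating. It also removes the
dimmest-gradient sharp events (disproportionately singlets), which biases
recovered WPA upward by ≈ +0.1 pp at the default composition; acceptable
against the ±0.3 pp recovery tolerance, and avoidable with a numeric focus
threshold.

The focus score is the RMS of the discrete intensity gradient magnitude of
the brightfield channel normalised by its mean intensity, computed after a
light Gaussian smooth (σ = 1 px). The smoothing matters: on shot-noise-
limited images the raw pixel-to-pixel gradient measures the Poisson noise,
not the edges, and sharp vs 3×-defocused events become inseparable.

In image mode (no annotations), coincidence exclusion uses a size rule: any
CD42b-negative connected brightfield object larger than 6 µm equivalent
diameter.

## Classifier

A small convolutional network on the CD42b channel only: two 3×3
convolution + 2×2 max-pool stages (16 then 32 filters), flatten, one
fully-connected layer of 64, 4-way softmax; cross-entropy loss, Adam
(lr 10⁻³), 24 epochs, batch 64. Implemented directly in numpy (im2col
convolutions) — small enough to train in ~2 minutes on one CPU. Brightfield
and CD62P are deliberately excluded from the input: aggregation class is a
morphological property, and the activation marker would leak the stimulation
condition into the label.

Baseline data is ~97.5 % singlets (~40:1 against the rarest classes), so
minibatches are drawn with inverse-class-frequency weights; unweighted
training collapses to the majority class. A stratified 20 % holdout is
scored after training (≥ 0.95 required by the tests; ~0.97 typical at the
default settings). Because singlets dominate real streams, singlet
specificity is what controls WPA bias — a 1 % singlet→doublet error rate
would inflate WPA by ~1 pp — and is tested separately (< 1 % required,
~0 % typical). Ties in the output probabilities break toward the smaller
class; training is deterministic given the config seed.

The deterministic oracle returns `min(n_platelets, 4)` from the annotation.
In image mode it counts platelets by enumerating disk-count hypotheses
n = 1..6 and fitting each as a sum of blurred disks (farthest-point +
weighted-Lloyd center initialisation, coordinate-wise radius grid search),
accepting the smallest n whose model RMSE over the bright footprint falls
below 0.08 of the single-disk interior level. Simple peak detection fails
here — tangent anti-aliased disks merge into one flat plateau — whereas the
model-fit counter is exact on noiseless renders of the construction
geometry. It assumes the rendering forward model and is for testing, not
for analysing real images.

## Quality control

Stage 1 (replicate concordance): for each donor and condition, both
technical-replicate WPA values must lie within 70–130 % of the pair mean,
read as a closed interval (a replicate at exactly 70 % is kept); any
violation, in any condition, excludes the donor entirely. Donors with a
missing replicate are excluded and counted separately. Stage 2 (day
consistency): per-acquisition-date means of baseline WPA over stage-1
survivors are screened by ROUT at Q = 1 %; by default all donors on a
flagged date are excluded (a per-donor mode exists). Stage order is fixed —
concordance first — and stage-1 exclusions are not re-tested.

The ROUT variant is the published robust-fit + FDR procedure specialised to
a constant model (K = 1): center = median; RSDR = 68.27th percentile of
absolute residuals × n/(n−K); residuals tested from most to least extreme
against two-tailed t-tail probabilities (n−K df) at stepwise levels
αᵢ = Q·(n−i+1)/n, stopping at the first non-significant one. Q = 0 flags
nothing; fewer than 3 values flags nothing with a warning.

## Statistics

Two-group contrasts: Shapiro–Wilk (α = 0.05) per group decides between
Welch's t (both normal; reported mean ± SD) and Mann–Whitney (reported
median with a distribution-free order-statistic 95 % CI). The Mann–Whitney
null is exact for combined n ≤ 20 (full enumeration when ties are present),
normal approximation with tie correction above. Age associations are OLS
regressions (R² = squared Pearson correlation, p from t with n−2 df),
optionally stratified by sex. The ADP response table reports per-class
cohort means, fold changes (undefined — NaN, never infinity — when a
baseline mean is 0), and paired contrasts on WPA and CD62P MFI (paired t or
Wilcoxon by normality of the differences). No multiple-testing correction
is applied anywhere; every p-value is nominal and must be read as such when
many outcomes are scanned.

## Problem sizes and tolerances

- Baseline-recovery experiment: 20 donors × 2 replicates at 2000 platelet
  events per measurement and a 2000-image training set. The class
  *proportions*, not the absolute event total, determine WPA; at 2000
  events the sampling SD of the cohort-mean WPA is ≈ 0.06 pp, small against
  the ±0.3 pp recovery band.
- Gate-rate experiment: 100 000 whole-blood events; the expected excluded
  fraction is the configured 99 % with binomial error.
- Calibration: 600 null regressions (n = 40 each) for the type-I check;
  20 seeded cohorts of 48 donors for slope-sign recovery.
- Classifier tolerances: oracle agreement and holdout accuracy ≥ 0.95;
  probability vectors sum to 1 within 10⁻⁶.

## Known limitations

- The renderer is a statistical emulation, not physical optics: no
  point-spread asymmetry, spectral bleed-through, flow-speed blur, or
  camera saturation; erythrocytes are annuli, not biconcave discs. Passing
  tests show the *pipeline logic* recovers planted truth under this model;
  they do not validate the classifier on real IFC images.
- The true coincidence-image rate and the instrument's focus-gate
  definition are unknown; both are free parameters here.
- Zero-dispersion cohorts are degenerate by design (deterministic counts);
  real replicate scatter is only represented with dispersion > 0.
- The exact donor-exclusion tallies of a real cohort depend on raw data
  this package does not model; the QC stages reproduce the rules, not any
  specific exclusion count.
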