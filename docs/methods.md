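# Methods

This document describes the models, the default parameters (with units
and rationale), the scope of the synthetic generators, and the numerical
choices. All defaults live in dataclasses (`SynthConfig`,
`PreprocessParams`, `WindowSpec`, `VHConfig`, `ExprFixtureConfig`) and
everything below can be changed by configuration.

## 1. Synthetic TMS–EEG cohorts (`synthetic_data`)

### Evoked model

Each subject s, condition c ∈ {single, paired} and region r has a source
amplitude `a(s, c, r)`; the sensor signal of a trial is

```
x(trial) = G @ (a(s, c, ·) ⊙ w(t)) + noise
```

where `w(t)` is a shared evoked waveform — a sum of exponentially
decaying sinusoids, zero pre-stimulus, unit peak, with default
components (2.5 Hz, τ = 350 ms), (8 Hz, τ = 60 ms), (25 Hz, τ = 25 ms)
chosen so the compound peaks near 90 ms, inside the 50–120 ms analysis
window — and `G` is the leadfield (sensors × sources). Sensor noise is
white in time and independent across channels (`noise_sd` 20 µV per
sample), plus a per-subject common spatial component; channels carry
random gains in (0.8, 1.2).

### Planted effect calibration

The ICF index of subject s at region r (paired-minus-single amplitude) is

```
icf(s, r) = icf_gain · profile_r + σ_b · ε(s, r) − 1[TRD] · d · σ_b · profile_r
```

with ε iid N(0, 1) per subject and region and σ_b =
`between_subject_sd`. Both groups share the same variance, so the
standardised HC − TRD difference is **exactly** `d · profile_r` at the
amplitude level: no Monte-Carlo tuning enters the calibration. The
propagation profile peaks (value 1) at the stimulated region
(rostralmiddlefrontal, the left DLPFC proxy) and decays with
centroid distance. Because the sensor noise is white in time, its
contribution to a 71-sample window mean is attenuated by √71 per trial
and further by trial averaging, so the measured standardised effect
tracks the planted d closely; `calibration.effect_recovery` verifies
this through the full evoked → dSPM → region → window pipeline
(recovered mean d = 0.525 for planted 0.52 over 200 cohorts).

### Leadfield

When the channel count is at least the source count, the leadfield has
orthonormal columns (QR of a random Gaussian matrix, scaled by
`leadfield_scale` = 40 µV per unit source): zero source crosstalk and
condition number 1, which keeps the planted regional effect identifiable.
With fewer channels than sources the generator falls back to SVD
clipping to condition ≤ 50; dSPM crosstalk then attenuates regional
effects — use ≥ 34 channels when the regional t-map is the quantity of
interest.

### Artifacts and clinical table

`ArtifactSpec` plants, per subject and condition, disjoint sets of
(i) bad channels (gain × 50), (ii) bad epochs (1500 µV deflection
outside the pulse window) and (iii) TMS pulse transients (5000 µV inside
−5…30 ms), all enumerated in the ground truth. The clinical table has
exactly 40% female participants per group, ages ~N(45, 12.5) in both
groups, MADRS ~N(32, 7) clipped at ≥ 18 and illness duration ≥ 0.5 years
(TRD only; HC scores are missing by design).

## 2. Preprocessing (`preprocess`)

Chain order (each step appends a log record):

1. **Baseline correction** — subtract the per-trial, per-channel mean of
   (−500, −150) ms.
2. **Bad-channel detection** — per-channel robust scale
   (1.4826 × MAD of the channel's samples) computed on the
   **pre-stimulus window** (−500, −15 ms), standardised across channels
   by a robust z with a relative-spread floor of 0.05; |z| > 3 flags the
   channel. Channels near the stimulation site
   ({F5, F3, F1, F7, AF3, FC3, FC5}) are protected from flagging. The
   robust statistic (rather than SD) is essential because high-amplitude
   transients are spatially global and inflate every channel's SD
   almost equally; the pre-stimulus restriction makes the score a
   property of recording noise, not of evoked projection strength.
   `sd`, `variance` and `ptp` remain configurable alternatives.
3. **Epoch rejection** — remove trials whose max |voltage| (flagged
   channels and the excision window masked out) exceeds 1000 µV.
4. **Pulse excision** — cut (−5, 30) ms and reconstruct each channel by
   a least-squares cubic fit to 20 ms of context on each side
   (reconstruction is exact to < 10⁻⁶ µV for cubic signals).
5. **Filter + resample** — polyphase downsampling to 1 kHz, then
   zero-phase order-4 Butterworth band-pass 0.5–100 Hz and band-stop
   48–52 Hz (second-order sections, `sosfiltfilt`). Filtering is not
   idempotent; the log records that.
6. **Bad-channel interpolation** — spherical splines via MNE
   (standard 10-05 montage positions).
7. **Average re-reference** — subtract the cross-channel mean per
   sample (idempotent, exact to < 10⁻⁹ µV).

## 3. Source estimation (`source_inverse`)

Noise covariance: Ledoit–Wolf shrinkage on baseline samples
(−500, −15 ms) pooled across trials and conditions. Inverse operator
with source covariance R = I and λ² = 1/9 (≙ SNR 3):

```
K = R Gᵀ (G R Gᵀ + λ² C)⁻¹       z(t) = K x(t) / sqrt(diag(K C Kᵀ))
```

solved by `scipy.linalg.solve` on the symmetric system (no explicit
inverse). The division by the per-source noise projection makes z a
noise-normalised (dSPM) estimate: applied to pure baseline noise its
per-source variance is ≈ 1 (the acceptance suite asserts within
[0.5, 2]). Optional `rescale_source_cov` sets R = ρI with
ρ = n_ch / trace(Gᵀ C⁻¹ G), which makes the **kernel** exactly invariant
to a global rescaling of C (the z time series itself necessarily scales
as 1/√c when C → cC; no formulation avoids that). Region series are the
signed mean of member-source z; the ICF-dSPM index is the 50–120 ms
(inclusive) window mean of the paired-minus-single region series.

## 4. Group statistics (`group_stats`)

Pooled two-sample Student t (df = n₁ + n₂ − 2), Cohen's d with the
pooled SD, Pearson χ² without continuity correction, Pearson (default)
or Spearman clinical correlations with NaN-pair removal. The regional
t-map is HC − TRD per region. One exclusion list applies globally to
sensor, source and clinical analyses.

## 5. Expression pipeline (`expression_pipeline`)

AHBA-style chain: (i) background filter — keep probes above background
in ≥ 50% of samples (boundary inclusive); (ii) sample assignment —
nearest region centroid within 2 mm (inclusive), left hemisphere only;
(iii) differential stability — DS(probe) = mean over donor pairs of the
Pearson correlation between regional mean-expression profiles; the
max-DS probe represents each gene and genes below the 50% DS quantile
are dropped; (iv) matrix build — within-donor scaled-robust-sigmoid
normalisation (z-score/identity alternatives), average within region,
then across donors, into a genes × 34 matrix. DS needs region
assignments, so assignment is computed before DS; since assignment is
probe-independent the surviving set is identical under either ordering.

The synthetic fixture plants: probes failing background, far (> 2 mm)
and right-hemisphere samples, a noisy second probe per selected gene, a
stable/unstable gene split straddling the DS cutoff, and marker genes
whose profiles have an **exactly** planted correlation with a target map
(Gram–Schmidt construction), all enumerated in the ground truth. The
pipeline's survivors are asserted to equal that truth exactly.

## 6. Virtual histology (`virtual_histology`)

Observed statistic per cell class: mean over its marker genes of the
correlation between the gene's 34-region profile and the t-map. Null:
`n_resamples` (default 10⁵, study scale 10⁶) random same-size gene sets
drawn without replacement from the surviving-gene pool; since the
statistic is a mean of per-gene correlations, these are precomputed once
and each draw is an average of a random subset (vectorised via
random-key `argpartition`). Two-sided p: add-one doubled smaller tail,
`min(1, 2·min(tail))`, never exactly 0. Family-wise control: Bonferroni
at 0.05/9 ≈ 0.0056. An exhaustive enumeration over all combinations
serves as an independent oracle for small pools;
`calibration.resample_enumeration_agreement` checks the resampled p
against it on the Monte-Carlo-error scale.

## 7. Calibration (`calibration`)

Monte-Carlo operating characteristics over freshly generated cohorts and
fixtures: planted-effect recovery (mean d, positive-t fraction), type-I
error of the group contrast under the null configuration (measured
0.045 at α = 0.05) and of the virtual-histology test on null fixtures
(measured 0.051), and resampling-vs-enumeration agreement. Replicate
cohorts use a reduced size (8 trials, 40 channels, 250 Hz) with the full
effect structure; since the standardised effect is dominated by
between-subject variance, the calibration is insensitive to trial and
channel counts.

## 8. Generator scope and limitations

- The leadfield is spatially **unstructured** (random orthonormal):
  ideal for identifiability and kernel oracles, but spherical-spline
  channel interpolation cannot truly reconstruct a lost sensor, so
  cohorts where every subject has bad channels show attenuated group
  effects after cleaning. Channel detection/interpolation is therefore
  validated on dedicated fixtures, and the narrative demo plants bad
  epochs and pulse transients but not bad channels.
- Single-cohort t-maps at the study's effect size (d = 0.52, n = 88)
  carry signal SD ≈ 0.4 against unit region noise, so the map's peak
  often falls off the stimulated region and map-based virtual histology
  has modest power; this is a property of the design, not of the
  implementation (the analysis narrative contrasts the measured map with
  the noise-free expected map to make this visible).
- Sensor noise is white in time; there is no 1/f background, eye/muscle
  artifact model, or recharge artifact beyond the planted pulse
  transient.

## 9. Numerical choices

- `scipy.signal.sosfiltfilt` (zero-phase, second-order sections) for all
  filtering; `resample_poly` for sample-rate conversion.
- `sklearn.covariance.LedoitWolf` for noise covariance;
  `scipy.linalg.solve` (symmetric) for the inverse operator.
- `scipy.spatial.cKDTree` for nearest-centroid sample assignment.
- Exact planted correlations and exact survivor bookkeeping in the
  generators, so tests can assert equality rather than tolerance bands
  wherever the quantity is deterministic.
- Seeded `numpy.random.default_rng` everywhere; identical configuration
  and seed reproduce cohorts, fixtures and manifests byte-for-byte.
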