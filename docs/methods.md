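# Methods

This note documents the models, estimators, defaults and numerical choices
behind `motorunit`, and what the synthetic cohorts do and do not establish
about real data.

## Track model and kinematic estimators

Tracks are one-dimensional positions along the axon axis, in µm, on a
uniform time grid. The soma lies toward −∞, so *retrograde* motion is a
negative position increment and *anterograde* positive; this convention is
stated once here and used everywhere. Axons confined to microgrooves are
quasi-1D and every statistic computed is speed- or displacement-based, so a
second coordinate column in input files is accepted and ignored.

Frame-grid validation uses a relative tolerance of 1e-6 on the frame
interval. Tracks with dropped frames are rejected, not interpolated:
interpolation would fabricate slow steps and silently alter stop counts.

Estimator definitions and the choices behind them:

- **Stops.** A stop is ≥ 3 consecutive inter-frame steps with speed
  strictly below 0.1 µm/s. Both constants are exposed; the inequality is
  strict, so a step at exactly the threshold never pauses, and runs of 1–2
  slow steps are not stops.
- **V_inst** is the mean step speed over steps outside detected stops. The
  rationale: instantaneous velocity and stop count are reported as separate
  axes of change, which requires decoupling movement speed from pausing.
  The alternative (include paused steps) is available via
  `include_paused_steps=True`. A consequence worth knowing: pauses shorter
  than the 3-step stop definition leak into V_inst and bias it slightly
  below the true run speed (about −0.03 µm/s at the default pause rates);
  on pause-free cohorts the estimator is unbiased.
- **V_avg** is |net displacement| / elapsed time, not path length — the
  inclusion criterion and the velocity distributions describe processive
  transport. A path-length variant sits behind `path_length=True`.
- **Inclusion filter:** duration strictly greater than 10 frames AND
  V_avg ≥ 0.2 µm/s inclusive, exactly as the criteria are printed
  upstream. Filtering is idempotent.
- **MSD** is the per-track time average with overlapping windows,
  MSD(k) = mean_i (x_{i+k} − x_i)², lag 0 omitted; the ensemble curve
  averages per-lag across the tracks long enough to contribute, with SEM
  over tracks (0 where one track contributes). Overlapping time averaging
  is standard single-particle-tracking practice; closed forms pin the
  estimator (pure run: MSD(k) = (v k Δt)²; pure localization noise σ with
  no drift: MSD(k) → 2σ²).
- **Velocity histograms** bin per-track V_avg at a caller-chosen width;
  fractions are normalized to sum to 1. The polynomial fit is ordinary
  least squares on bin centers vs fractions, default degree 3 (the degree
  of the reference overlay is not specified anywhere; 3 is the lowest
  degree that can follow a skewed unimodal shape). The degree is clamped to
  n_bins − 1 when few bins are occupied.
- **Directionality** calls retrograde/anterograde when |net| exceeds
  1 µm (default), else stationary; a track whose steps are all inside stops
  is stationary regardless of net.
- **Co-transport** between two channels sharing a frame grid: maximal runs
  of ≥ `min_frames` frames with |x_a − x_b| < `dist_um`.

## Contraction calling

The raw readout is the per-frame intensity of a fiber ROI. The baseline is
the trace median — robust against the bursts themselves — and deviations
are relative: (value − baseline)/baseline. The burst threshold is
k = 5 robust standard deviations, where the robust SD is 1.4826 × MAD of
the normalized trace; an event needs ≥ 2 consecutive supra-threshold
frames. At k = 5 and 1000 frames the false-event rate on Gaussian noise is
far below 1% (two consecutive 5σ exceedances). If the MAD degenerates to
zero while deviations exist (a flat trace with injected bursts), detection
falls back to an absolute relative-deviation threshold of 0.2 and warns.

A fiber is *contracting* with ≥ 2 events. The underlying categorization is
binary with no published numeric rule; requiring multiple bursts mirrors
what an active fiber's trace looks like, and the event list on every call
keeps single-event fibers auditable. All three constants are CLI-exposed.
The upstream convention that only fibers overlapped by at least one axon
are analyzed is a roster decision made before this module; the module
trusts the input roster.

## Morphology scoring

Healthy-NMJ percentage is computed only over colocalized (pre AND post)
events: 100 × intact-axon colocalizations / colocalizations, per chamber.
Non-colocalized events never affect the score. In vivo innervation is
100 × (post sites with pre present) / post sites, per muscle. Units with
an empty denominator are excluded with a warning rather than scored 0 or
100.

Aggregate density is count/area per section, summarized as mean ± SEM per
group and gray/white compartment. Percent change is 100 × (1 −
group/reference) with the disease-vehicle group as the natural reference
for treatment effects. Pooling is at section level by default with a
per-animal option (`by="animal"`), since published sample sizes mix both
conventions; both modes are reported by the CLI where animal IDs exist.

Fiber-diameter summaries are arithmetic (mean, SD, SEM, n) with pairwise
mean differences. `blind_labels` supports blinded scoring; scoring is
label-equivariant by construction and tested.

## Survival and statistics

Percent surviving is 100 × count(day)/count(first day observed), per
explant; the baseline maps to exactly 100 and the quantity is invariant to
count rescaling. Group timecourses aggregate explants present at each day,
mean ± SEM at explant level (the alternative — per-experiment SEM — is a
caller-side grouping decision).

Student's t defaults to the pooled-variance classical form, two-sided;
Welch sits behind `equal_var=False`. One-way ANOVA uses the standard F;
Fisher's LSD post hocs are unadjusted pairwise t statistics on the pooled
MSE with N − k degrees of freedom. LSD is *protected* by default (post hocs
withheld unless the omnibus F is significant at α = 0.05), the classical
convention when the protocol does not say otherwise; `protected=False`
always reports them. Identities pinned by tests: k = 2 ANOVA reproduces the
pooled t exactly (F = t², equal p), and both tests hold their nominal 5%
size within (0.04, 0.06) over 10⁴ Gaussian null simulations.

## Synthetic cohorts: what they emulate

Generators reproduce the sampling structure of each assay, not its imaging
physics:

- **Transport:** two-state (run/pause) Markov dynamics with per-frame
  Bernoulli switching, i.e. geometric dwell times — the simplest process
  that produces stop counts and run lengths. Per-step run speeds are
  Gaussian (clipped at 0), direction is fixed per track (retrograde with
  probability `retrograde_fraction`), and Gaussian localization noise is
  added per frame. Frame grid: 3 s × 100 frames (20 frames/min, 5-minute
  movies). Defaults: run speed 0.8 ± 0.2 µm/s, pause entry 0.05/step,
  pause exit 0.3/step, retrograde fraction 0.9, noise 0.02 µm. The absolute
  speed and pause magnitudes are **free parameters** — the assay's printed
  outputs are group comparisons, not absolute velocities — chosen as
  typical dynein-cargo kinematics and documented here once.
- **Contraction:** baseline 1.0 + Gaussian noise (σ_rel 0.02) at 30 fps ×
  1000 frames; contractors add a Poisson number of rectangular bursts
  (rate 0.25 Hz over the 33 s movie ⇒ ~8 expected events ⇒ the
  probability of fewer than two bursts, which would make a true contractor
  uncallable, is ~0.2%), amplitude 0.5 relative, 5 frames long,
  non-overlapping placements. Amplitude must exceed noise by construction
  or the ground truth would be undetectable.
- **NMJ events:** independent Bernoulli draws. In vitro mode draws axon
  intactness of colocalized events; in vivo mode draws presynaptic
  presence over postsynaptic sites.
- **Explant survival:** sequential binomial thinning of the previous day's
  count by the fraction ratio — counts are non-increasing by construction
  and the marginal mean at each day is initial × fraction(day). Days
  7/10/12/14/16 with the baseline at day 7. The disease trajectory
  (1.0, 0.95, 0.85, 0.68, 0.5) pins 50% loss at day 16 and starts the
  decline after day 10; the intermediate values are free shape choices.
- **Aggregates:** Poisson(density × area) per section. The absolute
  density scale (vehicle 20/mm²) is free; the treated preset is pinned at
  half the vehicle density.
- **Fibers:** Gaussians truncated at 0. Absolute means are free (disease
  30 µm, SD 6 µm); the treated preset is pinned 4 µm above disease-vehicle
  (5 µm in the healthy pair).

Named presets pin exactly the group-level observables of the study
conditions: contracting fraction 0.74 (healthy co-culture) vs 0.10 (no
MNs); intact-NMJ probability 0.75 in vitro; day-16 surviving fraction 0.5;
in vivo innervation 1.0 / 0.40 / 0.80 for healthy-vehicle,
disease-vehicle and treated; aggregate density ratio 0.5; fiber-diameter
offset +4 µm.

Because units are independent and noise is Gaussian/Poisson/Bernoulli,
passing recovery tests shows the *estimators* are unbiased and correctly
scaled at these cohort sizes — it does not show robustness to correlated
fibers within a chamber, drifting baselines, photobleaching, tracking
errors, or segmentation bias, none of which the generators model.

## Randomness and reproducibility

Every stochastic function takes a seed (int, `SeedSequence` or
`Generator`); cohort generators spawn one independent child stream per unit
via `SeedSequence.spawn`, so a whole cohort is reproducible from one
integer and units are statistically independent. Identical (params, seed)
give bit-identical outputs. CLI runs write a manifest JSON capturing the
command, configuration, seed, SHA-256 input hashes and output list.

## Problem sizes

The recovery experiments (shared by the test suite and
`scripts/acceptance.py`) use the study cohort sizes: 40 chambers × 30
fibers (contraction), 30 chambers × 50 events (in vitro NMJ), 200 explants
of 40 motor neurons (survival), 5 muscles × 100 NMJs per group (in vivo),
50 one-mm² sections per group (aggregates), 500 fibers per group
(diameters), each across 10 replicate seeds. Oracle-equivalence checks run
1000 randomized instances per operation at track lengths ≤ 60; test
calibration uses 10⁴ null simulations at n = 10 per group.

## Known limitations

- All statistics assume uniform frame intervals; variable-rate acquisitions
  must be resampled upstream.
- V_inst's stop exclusion interacts with the 3-frame stop definition as
  described above; comparisons across conditions are unaffected as long as
  the same settings are used.
- The MSD estimator's overlapping windows correlate adjacent lags; SEM per
  lag is over tracks, not an effective-sample-size correction.
- Fisher's LSD makes no multiplicity adjustment beyond protection by the
  omnibus F; with many groups, stricter corrections may be warranted.
- The synthetic generators draw independent units and stationary noise;
  see above for what recovery on them does not establish.
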