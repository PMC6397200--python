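# motorunit

Quantification pipelines for compartmental motor-unit assays, plus seeded
synthetic cohorts for validating every stage end to end.

Motor neurons (MNs) cultured with skeletal myofibers in microfluidic
chambers form functional neuromuscular junctions (NMJs), and ALS models
(mutant SOD1^G93A^) disrupt this system at several measurable levels:
axonal transport of neurotrophin cargo slows and pauses more, fewer
myofibers contract, NMJs degenerate, motor neurons die back, mutant-SOD1
aggregates accumulate in the spinal cord, and muscle fibers atrophy. This
package implements the descriptive statistics that turn the raw readouts of
those assays — particle tracks, intensity traces, colocalization event
tables, cell counts, section counts, diameter lists — into the group-level
numbers such studies report, for researchers running co-culture or
histology experiments who need a reproducible, scriptable analysis path.

## What it computes

**Track kinematics** (`motorunit.kinematics`). For a 1-D track
x(t_i) sampled at uniform Δt (position in µm along the axon axis, soma
toward −∞ so retrograde = negative increments):

- step speeds s_i = |x_{i+1} − x_i| / Δt;
- stops: maximal runs of ≥ 3 consecutive steps with s_i < 0.1 µm/s;
- instantaneous velocity V_inst = mean step speed outside stops
  (a switch includes paused steps);
- average velocity V_avg = |x_N − x_1| / (t_N − t_1);
- run lengths: |net displacement| of each stop-free stretch;
- time-averaged MSD(k) = ⟨(x_{i+k} − x_i)²⟩_i with overlapping windows,
  plus per-lag ensemble mean ± SEM across tracks;
- inclusion filter: duration > 10 frames and V_avg ≥ 0.2 µm/s;
- V_avg histograms with a least-squares polynomial fit, net directionality
  calls, and co-transport intervals between channel pairs.

**Contraction calling** (`motorunit.contraction`). Traces are normalized to
relative deviation from the median baseline; bursts are runs of ≥ 2 frames
with |deviation| > 5 robust SDs (1.4826·MAD); a fiber is *contracting* with
≥ 2 bursts, and chambers report 100 · contracting / analyzed.

**Morphology scoring** (`motorunit.morphology`). Healthy-NMJ percentage
(intact-axon colocalizations / all colocalizations), in vivo innervation
percentage (pre⁺ post sites / all post sites), aggregates-per-mm² densities
with percent change vs a reference group, fiber-diameter summaries with
pairwise mean differences, and a label-blinding helper.

**Survival** (`motorunit.survival`). Per-explant percent surviving
(100 · count(day)/count(baseline)), group timecourses, pooled-variance
Student's t, and one-way ANOVA followed by Fisher's LSD post hoc tests
(protected by default).

**Synthetic cohorts** (`motorunit.synthetic`, `motorunit.presets`). Seeded
generators emulate each assay — run-and-pause Markov cargo motion at 3 s
frame interval, baseline-plus-burst traces at 30 fps × 1000 frames,
Bernoulli NMJ events, binomially thinned explant counts over days
7/10/12/14/16, Poisson aggregate counts and truncated-Gaussian fiber
diameters — with named condition presets pinned to the group observables of
healthy, diseased, and drug-treated conditions.

## Worked example

```python
from motorunit import (TransportParams, simulate_chamber_tracks, summarize_tracks,
                       ContractionParams, simulate_intensity_traces, analyze_traces)

tracks = simulate_chamber_tracks(TransportParams(), n_tracks=200, seed=7, condition="WT")
print(summarize_tracks(tracks).cohort.round(3).to_string(index=False))

traces, truth = simulate_intensity_traces(ContractionParams(fraction_contracting=0.74),
                                          n_fibers=30, seed=7, chamber_id="c01")
calls, pct = analyze_traces(traces)
print(f"contracting: {sum(c.contracting for c in calls)}/30 "
      f"({pct['c01']:.1f}%), ground truth {sum(truth)}/30")
```

prints

```
condition  n_tracks  v_inst_mean_um_s  v_inst_sem_um_s  v_avg_mean_um_s  v_avg_sem_um_s  stop_count_mean  stop_count_sem  run_length_mean_um  fraction_retrograde
       WT       200             0.775            0.002            0.689           0.004             2.03           0.086              89.988                 0.91
contracting: 24/30 (80.0%), ground truth 24/30
```

All 200 simulated tracks pass the inclusion filter; the recovered V_inst
(0.775 ± 0.002 µm/s) sits at the generator's 0.8 µm/s run speed minus the
small leak from pauses shorter than the 3-frame stop definition, V_avg is
lower because pauses dilute net progress, tracks pause about twice per
5-minute movie, and 91% are retrograde. In the contraction chamber the
caller recovers the ground truth exactly: 24 of 30 fibers contracting (80%
in this chamber, drawn from a 74% condition).

The same pipelines are available from a shell:

```bash
motorunit simulate --assay contraction --preset WT_cocult --n 10 --seed 1 --out sim/
motorunit contraction --in sim/traces.csv --out results/
```

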