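# chlorokin

Zone-resolved chlorophyll-fluorescence kinetics of de-etiolating seedlings:
simulation, segmentation, time-resolved statistics, and 77 K spectral
decomposition.

## The problem

When a dark-grown (etiolated) seedling first sees light, it starts making
chlorophyll. A pulsed-fluorescence imaging assay can follow this greening
non-destructively and with high time resolution: a short blue actinic pulse
(50 ms, 470 nm, 240 µmol photons m⁻² s⁻¹) both initiates greening and
excites chlorophyll fluorescence (detected at 680–750 nm); one pulse every
2 min for 4 h yields 120 frames whose pixel intensities track chlorophyll
amount, because photosynthetic electron transport — and with it variable
fluorescence — is not yet active. `chlorokin` is for plant photobiologists
and phenotyping-pipeline developers who want an open, testable
implementation of the full measurement-and-analysis chain, including a
synthetic-data generator that stands in for the instrument.

The package provides:

- **protocol** — the pulse/round schedule, frame timestamps, light dose;
- **synthgen** — synthetic plate layouts, three-phase greening kinetics,
  rendered 16-bit image stacks with per-pixel ground truth, virtual
  destructive pigment tables (T0–T8), 77 K emission spectra;
- **segmentation** — reference-frame selection, background thresholding,
  cotyledon/hypocotyl/root zone partition, fixed-mask ROI trace extraction;
- **kinetics** — F/F0 normalization, replicate aggregation, phase
  annotation (burst end, lag end / exponential onset);
- **stats** — per-round mixed-model or Welch tests, Benjamini–Hochberg
  correction across the 120 rounds, significant time intervals, Pearson
  correlation of imaging kinetics against destructive pigment data;
- **spectra** — Gaussian decomposition of 77 K spectra into pigment–protein
  pools (free/photoactive protochlorophyllide, unbound chlorophyll, PSII
  core, LHC antenna) and pool-trend tracking.

## The model in brief

Zone fluorescence follows a three-phase curve
F(t) = F₀ + A(1 − e^(−t/τ)) + P[σ(r(t − t₀)) − σ(−r t₀)]
(burst with τ ≈ 4 min, lag, logistic exponential phase with onset t₀ ≈
90–120 min); protochlorophyllide decays to a minimum near 60 min and
re-rises after ~120 min. Traces are normalized per ROI to the first-round
mean (F/F0), aggregated over n = 9 replicate ROIs, and two variants are
compared round by round with BH-adjusted p-values; maximal runs with
p_adj < 0.05 are reported as significant time intervals. See
`docs/methods.md` for the full account.

## Worked example

Simulate a two-variant plate (wild-type-like vs a mutant whose exponential
onset is delayed from 120 to 150 min) at reduced 64×64 scale, then analyze
the rendered stack:

```yaml
# demo.yaml — everything omitted falls back to package defaults
image_shape: [64, 64]
layout: {grid_rows: 3, areas_per_row: 6, replicate_cells_per_variant: 9,
         seeds_per_area: 4, seedlings_per_cell: 3, plate_size_mm: [120.0, 120.0]}
variants:
  wildtype: {}
  mutant: {exp_onset: 150.0}
```

```sh
chlorokin pipeline --config demo.yaml --seed 11 --out demo/
```

Output:

```
wrote 120-page stack and ground truth to demo
1 significant interval(s) at alpha=0.05
analysis written to demo
```

`demo/intervals.csv` (header lines echo the config hash and protocol):

```
start_min,end_min
92.0,168.0
```

The pipeline flags 92–168 min as significantly different: the window where
the wild-type curve has entered its exponential phase while the delayed
mutant has not yet caught up — before 92 min both genotypes are still in the
lag phase, and after ~168 min the mutant has converged to the same plateau.
`demo/aggregate_wildtype.csv` shows the normalized kinetics (mean ± SD over
the 9 replicate ROIs): F/F0 = 1.0 at t = 0 by construction, 1.19 after one
round (the fast burst), ≈ 3.91 at the 4-h endpoint; the mutant plateaus at
≈ 3.85.

The same stages are available as a library:

```python
from chlorokin.pipeline import small_test_config, simulate_run, analyze_run

cfg = small_test_config(rng_seed=11, exp_onset_shift=30.0)
sim = simulate_run(cfg)
res = analyze_run(sim.stack, sim.layout, cfg)
print(res.comparison.intervals)   # [(96.0, 164.0)] — detected onset shift
```

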