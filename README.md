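# capdep

Single-molecule kinetics of actin filament pointed-end depolymerization by
CAP/Srv2 hexamers on Cofilin-decorated filaments.

Purified actin filaments depolymerize over minutes, yet cells turn their
actin networks over in seconds. Cyclase-associated protein (CAP, yeast
Srv2) resolves much of this paradox: hexameric CAP transiently occupies the
pointed end of a Cofilin-decorated filament and, while bound, drives subunit
loss two orders of magnitude faster than the spontaneous rate (~44 vs ~0.13
subunits s⁻¹). `capdep` implements the quantitative machinery of that
single-molecule TIRF analysis as a tested Python package:

- a **stochastic generator** of the experiment — two-state end occupancy
  (exponential gaps at rate k₍on₎·c, dwells at k₍off₎), Poisson subunit
  removal, Binomial(6, p) dye loading with photobleaching, camera noise,
  and optional rendered two-channel image stacks;
- the **trace pipeline** — 5×5 box spot integration with 19×19
  median-perimeter background subtraction, 0.71 s Savitzky–Golay smoothing,
  hysteresis dwell calling with a strict >4-frame filter;
- **rate-constant estimators** with the labeled-fraction correction
  m = f·m′ − (1 − f)/k₍off₎ for the mean inter-event gap, generalized to the
  detector's dwell floor, gap resolution and photobleaching
  (`capdep.detection_model`), so that k₍on₎ = 1/(m·c) is recovered without
  bias from traces in which ~22% of binding events are invisible;
- **photobleaching step counting** (penalized changepoint fit) and the
  zero-truncated Binomial(6, p) maximum-likelihood labeling model that
  supplies f;
- **velocimetry and saturation kinetics** — trajectory/kymograph slopes at
  2.7 nm per subunit, bound/unbound segmented velocities, and the
  Michaelis–Menten fit v = k₍cat₎·c/(K_M + c), from which the processivity
  per binding event follows as (k₍cat₎/K_M)/k₍on₎.

The model being tested throughout: the end is occupied a fraction
cK_A/(1 + cK_A) of the time (K_A = k₍on₎/k₍off₎), and depolymerization is
fast only while a hexamer is bound, so fractional occupancy should parallel
the fractional velocity c/(c + K_M) — which it does, at both 8.3 and 83 nM.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data with known ground truth (printed constants as truth;
fixed seeds). `python analysis/01_photobleach_labeling.py` through
`05_report.py` produce, on this machine:

```
labeled fraction f               0.782 ± 0.020   0.779
k_off (1/s)                      0.480 ± 0.024   0.450
k_on (1/M/s)                     1.175e+07 ± 1.0e+06 1.100e+07
K_M (nM)                         48.4 ± 3.1      50.0
k_cat (subunits/s)               52.4 ± 1.0      53.0
k_cat/K_M (subunits/M/s)         1.08e+09 ± 7.3e+07
subunits per binding event       92 ± 10
```

Reading the table: 78% of hexamers carry at least one dye (so one in five
binding events is invisible and the gap correction matters); a hexamer
stays ~2.2 s at the end (k₍off₎ ≈ 0.45 s⁻¹) and rebinds at the
diffusion-limited k₍on₎ ≈ 1.1 × 10⁷ M⁻¹ s⁻¹; the saturation fit gives
K_M ≈ 50 nM and k₍cat₎ ≈ 53 subunits s⁻¹; and each binding event removes
(k₍cat₎/K_M)/k₍on₎ ≈ 90–100 subunits — about 250–270 nm of filament per
visit of a ~40 nm hexamer.

The same pipeline is scriptable as a CLI
(`capdep all --seed 1 --out runs/replica`) or from Python via
`capdep.run_pipeline(RunConfig(...))`.

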