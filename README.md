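# curtainkit

Analysis toolkit for single-molecule **DNA curtains** experiments: arrays of
stretched, surface-tethered DNA molecules imaged by TIRF microscopy, with
fluorescently labeled proteins (a site-specific binder such as CTCF on its
binding sites, cohesin subunits SA1/SA2, or a transcribing T7 RNA polymerase)
appearing as diffraction-limited spots whose positions and lifetimes are
followed over time.

The central problem the package solves is **separating true dissociation from
photobleaching** when measuring how long a protein stays bound. A fluorescent
spot on an array of `N` binding sites disappears only when the *last* labeled
molecule is gone, and each fluorophore can vanish either by dissociation
(lifetime τ) or by photobleaching (lifetime τ_ν at full illumination, diluted
by the laser duty-cycle ratio `r` = off-time / on-time). The effective
single-fluorophore disappearance time is

```
λ = (τ⁻¹ + r⁻¹ τ_ν⁻¹)⁻¹
```

and with Cᵢ(t) = (1 − e^(−t/λ))ⁱ (the CDF of the maximum of `i` i.i.d.
exponentials) and binomial weights B(i, l, N) for a labeling ratio `l`, the
survival of a spot observed from a cut-off time `c` onward is

```
S(t) = 1 − Σᵢ₌₁..N [(Cᵢ(t) − Cᵢ(c)) / (1 − Cᵢ(c))] · B(i, l, N) / (1 − B(0, l, N))
```

Measurements taken at several frame delays (1, 4, 10, 40, 60 s at 100 ms
illumination) probe different mixtures of bleaching and dissociation; a
**global fit** shares τ_ν across all datasets, `r` across measurements at the
same delay, (N, l) per DNA substrate and τ per protein construct, so that the
photobleaching-corrected τ is identified even when bleaching dominates every
single measurement.

Around this core the package provides:

- **Kaplan–Meier survival estimation** with Greenwood variance and
  right-censoring, single-exponential lifetime fits and a two-tailed z-test
  for lifetime comparisons (`curtainkit.model_survival`);
- **photobleaching step counting** (BIC-guided change-point staircase fit)
  and step-count → molecule-number conversion via the labeling ratio
  (`curtainkit.bleach_steps`);
- **binding-position analysis**: pixel→bp calibration against the chromium
  barrier/anchor marks, 40-bin histograms, fold enrichment on annotated
  binding sites, AT-content tracks and wash-survival fractions
  (`curtainkit.kymo_positions`);
- **kymogram tracking**: sub-pixel spot localization, nearest-neighbour
  trajectory linking and MSD-based 1-D diffusion coefficients
  (`curtainkit.tracking`);
- **transcription-event analysis**: velocities, continuous / early-stop /
  snapback classification (10 kb and 0.5 kb thresholds), processive fractions
  with binomial CIs and Fisher exact tests (`curtainkit.transcription`);
- **seeded Monte-Carlo generators** for every stage with machine-readable
  ground truth (`curtainkit.synthetic`), used throughout the test suite to
  verify that each estimator recovers what was programmed.

## Worked example

Simulate the five-frame-delay dwell-time design (300 spots per delay, N = 4
sites, labeling ratio 0.52, true τ = 3000 s, τ_ν = 30 s) and fit it:

```
$ curtain simulate --seed 3 --out demo
wrote demo/spots.tsv and truth.json
$ curtain fit-survival --spots demo/spots.tsv --out demo/report.json
tau:wt = 3059.0 s ± 10.4
report: demo/report.json; curves: demo/report.curves.tsv
```

The recovered lifetime (3059 s ≈ 51 min) agrees with the simulation truth of
3000 s (50 min) to 2%, even though at the shortest frame delay the effective
spot lifetime is dominated by bleaching (r·τ_ν = 300 s ≪ τ). The report JSON
carries all shared-parameter estimates with standard errors; the curves TSV
holds each Kaplan–Meier curve next to the fitted model.

The same machinery from Python:

```python
>>> from curtainkit import molecules_from_steps, fisher_exact_2x2
>>> molecules_from_steps(8.8, 0.52)   # mean bleaching steps, labeling ratio
(16.92, 17)
>>> fisher_exact_2x2([[40, 1], [76, 71]])
4.004772797754087e-09
```

The first line converts a mean of 8.8 observed bleaching steps at 52%
labeling efficiency into ≈17 molecules per cluster; the second compares
event counts between two conditions.

Other subcommands: `curtain bleach` (step counting), `curtain enrich`
(binding-site fold enrichment from positions + FASTA/BED), `curtain track` /
`curtain diffusion` (kymogram TIFF → trajectories → D), `curtain transcribe`
(event classification) and `curtain run` (YAML-configured pipeline).

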