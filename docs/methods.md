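# Methods

## Dwell-time model

A fluorescent spot on an array of `N` binding sites disappears when the last
labeled molecule on it is gone. Two independent exponential channels remove a
fluorophore: dissociation with lifetime τ (wall-clock) and photobleaching
with lifetime τ_ν, which only advances while the laser is on. Under a framed
illumination schedule (`illumination_time` on, `frame_delay` off) the
bleaching channel is diluted by the duty-cycle ratio
`r = frame_delay / illumination_time`, giving the effective
single-fluorophore disappearance time λ = (τ⁻¹ + r⁻¹τ_ν⁻¹)⁻¹. The number of
labeled molecules per spot is Binomial(N, l) conditioned on ≥ 1 (unlabeled
spots are invisible), and observation starts at a per-measurement cut-off
`c`, the shortest reliably measured lifetime. Spot survival conditioned on
presence at `c` is

    S(t) = 1 − Σ_{i=1..N} [(C_i(t) − C_i(c)) / (1 − C_i(c))]
               · B(i, l, N) / (1 − B(0, l, N)),
    C_i(t) = (1 − exp(−t/λ))^i.

Assumptions: sites fill independently with labeled protein at probability
`l`; all fluorophores on a spot bleach and dissociate i.i.d.; bleaching is a
continuous-rate process with the duty cycle folded into λ (no per-frame
discreteness); no rebinding or blinking. C_i is treated as a CDF (its closed
form is one). The mixture weights are the *unconditioned* binomial weights
with per-component truncation at `c`; the alternative (posterior reweighting
of components by their survival to `c`) is deliberately not applied — the
Monte-Carlo oracle test compares the simulator against exactly this printed
form, and the simulator's default `truncation="component"` mode matches it
exactly, while `truncation="reject"` exists to probe the difference.

Infinite parameters are explicit sentinels: τ = ∞ (no dissociation) and
τ_ν = ∞ (no bleaching) are handled analytically, never as large numbers.

## Global fit

Each measurement's Kaplan–Meier curve (product-limit with Greenwood
variance; censored spots leave the risk set at the recording end) is fitted
jointly against S(t) evaluated at the observed event times. Sharing: one
τ_ν for all datasets; one `r` per distinct frame delay; (N, l) fixed per
DNA; one τ per protein construct; `c` fixed per measurement (default: its
smallest uncensored time).

- **Objective.** Weighted least squares with weights = inverse Greenwood
  variance floored at 1e−4 (the floor stops the earliest, near-zero-variance
  points from dominating). An `objective="mle"` mode (censored likelihood of
  the truncated mixture) is available but not the default: the measured
  object in this assay is the survival curve.
- **Parameterisation and optimiser.** All positive parameters are fitted in
  log-space with bounded trust-region least squares (`scipy`'s `trf`),
  multi-start (5 starts, ±35% log-uniform perturbations, seeded and recorded
  in the result). Standard errors come from the Gauss–Newton curvature at
  the optimum, scaled by the reduced χ².
- **The role of r.** With a single construct the data constrain exactly one
  effective λ per delay, so freeing τ, τ_ν *and* every per-delay `r` leaves
  τ structurally unidentifiable (any τ above max λ_d can be compensated by
  the r·τ_ν products). The default therefore **fixes r at the duty-cycle
  ratio** — the quantity it physically is — leaving τ and τ_ν as the free
  kinetic parameters (plus optionally l per DNA via `free_l`). `free_r=True`
  restores bounded per-delay r fitting ([r₀/10, 10r₀]) for sensitivity
  analysis; the fit then warns about the flat rescaling direction and breaks
  exact objective ties toward duty-cycle-consistent r values.
- **Under-identification** (a single frame delay with both τ and τ_ν free)
  is flagged with a warning on the result, never silently absorbed.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* of each measurement:
exponential disappearance with the duty-cycle-diluted bleaching channel,
conditioned binomial labeling, right-censoring at the recording end,
staircase bleaching with Gaussian noise, Brownian 1-D motion with a Gaussian
PSF and Poisson counts, and transcription traces honouring the 10 kb / 0.5 kb
class definitions. They do **not** model optics beyond a Gaussian PSF, dye
blinking or triplet states, drift, uneven illumination, or overlapping
spots. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to every imaging artefact
in real curtains data.

Default study conditions (chosen once): five frame delays (1, 4, 10, 40,
60 s) at 100 ms illumination; 300 spots per measurement; N = 4, l = 0.52;
τ = 3000 s with τ_ν = 30 s, so that bleaching dominates at the 1 s delay
(r·τ_ν = 300 s ≪ τ) and dissociation at the 60 s delay; recording end
3600 s (~25% censoring at the longest delay). The default substrate is a
deterministic 48,502 bp λ-like sequence built programmatically: a GC-leaning
left arm (~45% AT) and AT-rich right arm (~62% AT), with two cassettes of
four binding-site motifs (129 bp start-to-start spacing) at 15,000 and
28,000 bp — 13 kbp apart, opposite orientation, each falling inside a single
bin of the 40-bin layout — or a single site for the 1× variant; optional T7
promoters sit 150 bp upstream of each cassette.

In the bleach-staircase generator, inter-step waits are exponential
(mean 200 frames) with a 5-frame resolvability floor: two bleaching events
inside the same camera frame are physically one observable step, so a floor
is required for "exact step-count recovery" to be a well-posed score. Truth
records report the *realized* step times (steps whose waits run past the
recording do not occur), and detectors are scored against those.

## Numerical and algorithmic choices

- **Step detection**: greedy binary segmentation on within-segment RSS with
  a BIC stop (`n·ln(RSS/n) + (2k+2)·ln n` for k change points), followed by
  local change-point refinement and backward pruning; minimum segment length
  2 frames. Upward steps (blinking/rebinding) are detected but excluded from
  the bleaching count unless `include_upward=True`. The criterion and
  penalty live in one place (`_total_bic`) and are swappable.
- **Localization**: per-column threshold at median + 4·MAD (configurable),
  local maxima ≥ 3 px apart, sub-pixel refinement by a 1-D Gaussian fit on a
  ±3 px window with a centroid fallback.
- **Linking**: greedy nearest-neighbour within `max_step` bp per elapsed
  frame, bridging up to `max_gap` missing frames; candidate pairs are
  processed in order of displacement with ties broken on position, which
  makes the result invariant to detection order within a frame.
- **Diffusion**: time-averaged MSD at lags 1..4 (default), weighted linear
  fit, D = slope/2; the localization-error offset stays in the intercept.
  Because TA-MSD points share displacement pairs, the reported standard
  error is the closed-form sampling error of an MSD-slope estimate,
  se(D) = D·√(2(2n²+1)/(3n(N−n+1))) for n lags on N frames, not the
  residual-based fit error (which understates the uncertainty severalfold).
  A quadratic term whose contribution at the largest lag exceeds half the
  linear term flags ballistic (drift-like) motion.
- **Transcription calls**: snapback = any single-interval upstream
  displacement ≥ 500 bp; early stop = permanent termination strictly below
  10,000 bp; else continuous. "Permanent" means no forward motion beyond
  100 bp (≈1 pixel) for the remainder of the recording with a minimum dwell
  of 30 s — the dwell threshold is a declared convention separating pauses
  from stops. Calls are threshold-exact: ±1 bp at either boundary flips the
  class.
- **Fisher exact test**: two-sided p by summing hypergeometric probabilities
  ≤ that of the observed table (relative tolerance 1e−9 against
  floating-point ties); degenerate margins give p = 1.
- **Enrichment**: mean count per binding-site bin over mean count per other
  bin (per-bin densities, so the fold is independent of bin count); a bin
  counts as a binding-site bin if it overlaps a site feature by ≥ 1 bp; an
  empty background returns a flagged infinity.
- **AT classification**: AT-rich iff windowed A/T fraction ≥ 0.5 (boundary
  included); default window 500 bp, centred, truncated at the edges.
- **Coordinates**: 0-based half-open bp throughout; BED for features; times
  in seconds in all on-disk formats.

## Problem sizes

Validation runs use sizes at which the checks are statistically meaningful
yet quick: 10⁴ spots for the Monte-Carlo/model sup-norm comparison (< 0.02),
20 seeded replicates of the five-delay design for lifetime recovery
(median |τ̂−τ|/τ < 15%), 500 staircases for step-count recovery (≥ 95%),
200 Brownian trajectories of 500 frames for diffusion (median error < 20%),
n = 500 positions (median of 5 replicates) for 7×/16× enrichment recovery
(±15%), and cohorts of 200 traces for transcription fractions (binomial 95%
CIs).

## Known limitations

- The dwell-time model ignores dye blinking and rebinding; both would bias
  τ_ν estimates on real data.
- With `free_r=True` the τ_ν/r rescaling ridge means τ_ν is only pinned by
  bounds and tie-breaks; τ itself additionally requires ≥ 2 constructs or
  fixed r.
- The step counter assumes piecewise-constant plateaus; gradual decays or
  strongly correlated noise are outside its model.
- Greedy linking can mis-assign crossing trajectories; no motion model or
  global assignment is attempted.
- Single-exponential lifetime fits report curve-fit standard errors, which
  are optimistic when the KM points are strongly correlated at large t.
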