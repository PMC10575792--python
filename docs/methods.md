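# Methods

## The model

`casyn` couples the canonical phenomenological model of short-term synaptic
plasticity with a two-pool description of presynaptic calcium. The vesicle
variables are the readily releasable fraction `x` and the release
probability `u`:

    dx/dt = (1 - x)/τ_d - u·x·R
    du/dt = (U - u)/τ_f + U·(1 - u)·R
    w(t)  = u(t)·x(t)

with depression timescale `τ_d`, facilitation timescale `τ_f` and drive
`R`. The baseline release probability `U`, a free constant in the classical
formulation, is here a saturating function of the free calcium
concentration `c`:

    U(c) = 2/(1 + exp(-c/λ)) - 1

so that both calcium starvation (`U → 0`) and surplus (`U → 1`) plateau.
Free and bound calcium exchange through a buffer of finite capacity `B`:

    dc/dt = -c/τ_c - λ_cb·(B - b)·c + λ_bc·b + μ·R
    db/dt = -b/τ_b + λ_cb·(B - b)·c - λ_bc·b

Binding is only possible into the `B - b` unoccupied buffer slots; each
input event injects `μ` units of free calcium. Summing the two equations
gives the exact balance `d(c+b)/dt = μR - c/τ_c - b/τ_b`, which the
right-hand-side implementation preserves term by term and the tests check
both symbolically and along trajectories.

### Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| τ_d | depression recovery time | 0.2 | s |
| τ_f | facilitation decay time | 1.5 | s |
| τ_c | free-Ca clearance time | 100 | s |
| τ_b | bound-Ca turnover time | 10 000 | s |
| λ_cb | binding rate | 200 | 1/(conc·s) |
| λ_bc | unbinding rate | 30 | 1/s |
| μ | Ca influx per input event | — (required) | conc |
| B | buffer capacity | — (required) | conc |
| λ | sigmoid scale of U(c) | — (required) | conc |

Times are SI seconds throughout (`τ_d`, `τ_f` correspond to the literature
values of 200 ms and 1 500 ms). `c`, `b`, `μ`, `B` and `λ` share one
arbitrary concentration unit: absolute presynaptic concentrations are not
identifiable from the data this model is aimed at, only their ratios
matter. Because `μ`, `B` and `λ` have no canonical values they must always
be given explicitly (the TOML loader has no defaults for them and rejects
unknown keys).

For the package's own study conditions (tests, acceptance script) we use
`μ = 0.001`, `λ = 1`, `B ∈ [10, 1000]` at `R = 20 Hz`. Rationale: the
buffer-free steady state is then `c* = μRτ_c = 2`, i.e. order `λ`, placing
the system on the responsive flank of the sigmoid; and `μRτ_b = 200` sets
the scale at which buffer capacities saturate, so the sampled `B` range
spans under- and over-saturated buffers.

## Closed-form steady state

Under constant drive the fixed point solves, after eliminating `b` via its
nullcline `b* = B·τ_b·λ_cb·c*/(1 + τ_b(λ_bc + λ_cb·c*))`, a quadratic in
`c*`:

    (τ_b λ_cb) c² + [(1 + k_c) + k_b(B - μRτ_b)] c - μRτ_c(1 + k_c) = 0,
    k_b = τ_c λ_cb,  k_c = τ_b λ_bc,

and the vesicle variables follow algebraically:
`u* = U*(1+Rτ_f)/(1+U*Rτ_f)`, `x* = 1/(1+u*Rτ_d)`, `w* = u*x*`.

Numerical choices:

* The quadratic is solved with the cancellation-free formulation
  `q = -(B_c + sign(B_c)√disc)/2`, roots `q/A` and `C_c/q`; in the
  physiological regimes `|B_c|` reaches ~1e9 and the textbook formula
  loses all significant digits in one root.
* For `μR > 0` the root product `C_c/A` is negative, so exactly one root
  is non-negative. Stability is nevertheless verified dynamically, not
  assumed: the candidate root is displaced by `ε = 1e-6·max(1, c*)` with
  `b` slaved to the free-calcium nullcline, and `db/dt` must point back
  toward the root from both sides. Zero drive returns the rest state
  directly.
* Sweeps extract `(w_max, R_max)` on the discrete rate grid (logarithmic
  by default), with no interpolation.
* The bound-calcium axis of the `x*`-vs-`b*` curves is generated by
  varying `μ` at fixed `B` (drive strength as the knob); the grid is
  configurable.

The model's three qualitative predictions — `x*` non-increasing in `b*`
across sigmoid scales, `w_max` decreasing and `R_max` non-decreasing in
`B`, and convergence of all curves once the buffer saturates at high
drive — are asserted as monotonicity properties of these sweeps.

## Time integration

The system is stiff twice over: timescales span `τ_d = 0.2 s` to
`τ_b = 10⁴ s`, and the calcium exchange rates `λ_cb(B-b)` reach ~1e4/s.
Constant-rate integration therefore defaults to LSODA (`rtol 1e-10`).
Spike-train drive uses a fixed-step scheme in which a spike contributes
`R = 1/dt` on its step — a unit impulse, so Poisson-spike and
constant-rate drive agree in expectation; within each step the vesicle
pair is updated explicitly (its increments cannot leave `[0,1]` when
`R·dt ≤ 1`) and the calcium pair by a backward-Euler split (`c` first with
`b` frozen, then `b` with the new `c`), which is unconditionally stable
and preserves `c ≥ 0`, `0 ≤ b ≤ B` by construction. Roundoff-sized bound
violations (≤ 1e-9) are clipped; anything larger raises a
numerical-instability error advising a smaller step.

Whether spike-train mode should drive the vesicle equations with the same
impulses as the calcium influx is not settled by the verbal model
description; the implementation uses identical impulses for both.

## Image pipeline

Ion images are integer count grids (one per species per acquisition
layer). Layers are registered to the second layer with integer shifts
maximizing raw cross-correlation inside a configurable search radius
(default 10 px); there is no sub-pixel claim in the underlying protocol,
so none is implemented. Shifted layers are zero-filled and summed; a best
shift on the search boundary is an error, not a silent result. Pixel size
is `1000·raster_µm/pixels` nm/px (40 µm/256 px → 156.25, 50 µm/256 px →
195.3125, 70 µm/256 px → 273.4375).

ROIs are inclusive discs `(i-r₀)² + (j-c₀)² ≤ r²`; radius 6 gives exactly
113 pixels. Per ROI and channel the disc mean minus a per-channel scalar
background is recorded; discs that leave the image (or touch alignment
fill) are errors rather than partial means. The low-signal filter models
background-subtracted ⁴⁰Ca intensities as zero-mean normal noise with SD
`σ_bg` estimated from user-supplied background samples and removes ROIs
with value ≤ +1σ (one-sided — on pure noise this removes Φ(1) ≈ 84.1%); a
two-sided variant (`|v| ≤ σ`) is available by flag. The binding split
partitions retained ROIs at mean ⁴⁰Ca counts > 2.

Per-cell isotope enrichment is `1000·mean(⁴⁶Ca)/mean(⁴⁰Ca)` over a cell
mask, in per mil. Natural abundance puts this at
`1000·0.004/96.94 ≈ 0.0413‰`; a labeling source containing 5% ⁴⁶Ca caps it
at 50‰. Because single ⁴⁶Ca counts inflate low ratios, total counts are
reported alongside every ratio. ⁴⁸Ca is carried as metadata only.

## Traces

Fluorescence is normalized as `p(t) = 100·(F - F0)/(Fmax - F0)` with
`F0` the mean of the first 5 s and `Fmax` the mean of the terminal
ionomycin window (default last 15 s); both windows are configurable. The
burst detector is deliberately the simplest deterministic scheme
consistent with the verbal definitions (no published algorithm exists for
this assay): a burst is a maximal contiguous run of spontaneous samples
with `p > θ_burst` (default 5 %Fmax) containing at least one local
maximum of prominence ≥ `θ_prom` (default 10 %Fmax); those maxima are the
peaks. Stimulus windows and the plateau are excluded. Burst and peak
rates are normalized by the spontaneous duration only (stimulus time
excluded) — the alternative denominator (full recording) is a judgment
call; this one is flagged here as the package's choice. Peak metrics are
reported in %Fmax, per-burst summed intensity in `F/F0 - 1` units: the
unit mixture mirrors the assay's reporting conventions. Zero detected
bursts yield absent (None), not zero, burst metrics.

## Statistics

Ordinary least squares with the two-sided t-test on the slope (n−2 df),
two-tailed Pearson correlation, Bonferroni correction reported in both
conventions (`p·m` uncapped, as sometimes printed in figure legends, and
capped at 1 — capped is the summary default), and tie-corrected
Kruskal–Wallis with Dunn's post-hoc z-tests on joint ranks. Dunn
pairwise p-values are unadjusted by default with an optional Bonferroni
flag. The Bonferroni family size `m` is always an explicit input, never
inferred. Degenerate constant-`y` regression returns slope 0, R² = 0,
p = 1 instead of erroring so batch pipelines keep running; constant `x`
is an error. For simple regression the slope p equals the Pearson p
(algebraic identity), which the tests use as a cross-check; Dunn's test
is additionally checked against hand-computed rank examples and the
two-group identity `H = z²`.

## Synthetic data

The generators produce every input format the pipeline reads, with the
planted truth returned alongside: Poisson ion-count stacks (smooth
Gaussian-source truth fields, integer inter-layer shifts, ⁴⁶Ca field =
⁴⁰Ca field × enrichment/1000), ROI tables with a two-population
calcium-binding mixture (default binding fraction 0.183) and linear
channel relations with configurable — including negative — slopes,
per-cell turnover ratios from Poisson count pairs bounded by the 50‰
source ceiling, indicator traces with planted non-overlapping bursts
(triangular peaks on a pedestal at 60% of burst amplitude, so sub-peak
prominence is 40% of amplitude), two stimulus windows and a terminal
plateau, and homogeneous Poisson spike trains. Noise models are Poisson
for counts and Gaussian for fluorescence, matching the respective
detection physics and keeping the oracles analytic.

Defaults are sized for fast suites: 64×64 images (not the instrument's
256×256), 3 layers, shifts within ±3 px, ~300 s traces at 1 Hz. What the
generators do *not* emulate: spatial autocorrelation of real cell
morphology, detector dead-time and quasi-simultaneous-arrival effects,
fluorescence bleaching and focus drift, or the empirical intensity
distributions of real stained cultures (no such data ship with the
package). Recovery results on synthetic data therefore validate the
pipeline's arithmetic and statistical calibration, not its robustness to
those real-data artifacts.

## Problem sizes in the acceptance script

`scripts/acceptance.py` recomputes everything from scratch with a single
seed: 20 random parameter draws for the analytic-vs-ODE check (each
integrated to 5×10⁵ s), 6-point buffer sweeps on 60-point rate grids, 200
alignment trials, a 200-ROI regression recovery, 50 000 noise samples for
the filter fraction, and 1 000 Monte-Carlo replicates per type-I-error
estimate. These sizes keep the full run around ten seconds while leaving
the Monte-Carlo standard errors well inside the asserted bands.

## Known limitations

* The model is mean-field: no stochastic vesicle counts, no postsynaptic
  side, no spatial calcium gradients.
* Integer-only registration; hand alignment between fluorescence and ion
  images is replaced by a supplied transform, and interactive ROI
  clicking by CSV center lists.
* The steady-state stability test is a local sign test, not a bifurcation
  analysis; it diagnoses (rather than handles) parameter pathologies where
  zero or two roots pass.
* Absolute calcium concentrations are out of reach without calibrated
  standards; everything is in relative units.
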