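# Methods

## Model and assumptions

`brbud` estimates an animal's utilization distribution (UD) from serially
correlated relocations by treating each pair of successive fixes as a
*biased random bridge*: a biased random walk (independent headings drawn
around a preferred direction, hence a drift `v` plus diffusion `D`)
conditioned on both endpoints. Two simplifications make the bridge usable
in practice:

1. **Isotropy.** The diffusion anisotropy induced by the drift is neglected,
   so the pinned density at activity time `t` is a circular Gaussian centred
   on the chord point `μ_B(t) = z_0 + (z_T − z_0) t/T` with per-axis
   variance `2 D t (1 − t/T)`. This is exactly the Brownian-bridge pinned
   density; the drift drops out of the expression entirely, which is what
   makes the method applicable without ever estimating `v` per bridge.
2. **Piecewise-constant drift.** The drift may change freely between
   bridges but must be constant within one. This is enforced by the
   recording-time threshold `T_max`: segments with `T_R > T_max` are
   excluded from the UD (their activity time is removed from all sums) and
   the movement standard deviation is consequently capped at
   `β_Tmax = (D T_max/2)^0.5`.

Time inside bridges is *activity time*, `T_i = P_i T_R(i)`: resting time is
ignored by default. The relocation variance floor `σ_min²` represents
habitat grain and the positional uncertainty of the animal relative to the
recorded fix (not GPS device noise), and enters the total variance either
with constant weight (`σ_min² + 2Dt(1 − t/T)`) or by progressive merging
into the movement component. The merging form requires
`D > 2σ_min²/T_max`; we take that bound as strict and validate it at
construction. The merging form depends (mildly) on `T_max`; the
constant-weight form is provably independent of it, which the tests assert
exactly.

The UD itself is computed by the MKDE route: each included segment is
divided into `n_i = round(T_i/τ)` equal activity-time intervals, and every
recorded or interpolated location receives a circular Gaussian kernel with
bandwidth `h_i(m) = σ_tot(m T_i / n_i)`, summed with equal weights `1/N_L`.
With a constant `τ`, the number of locations per segment is proportional to
`T_i`, so equal weights realise the required time weighting; the kernel sum
is a discretization (in `t`) of the time-averaged bridge density, and the
test suite checks it against direct midpoint quadrature of that integral.

Parameter estimation uses method-of-moments identities on relocation
triplets and single segments: `E[δ²] = 4 D T_i T_{i+1}/(T_i + T_{i+1})`
for the diffusion coefficient (with couples dismissed when activity times
or lengths differ by more than a factor of two, or when
`T_R(i) + T_R(i+1) > T_max`), and `E[L²] = v²T² + 4DT` for habitat-specific
squared drift speeds. Negative `v²` estimates are reported as such — they
indicate a habitat whose own diffusion coefficient is below the global one
— and never silently clipped.

## Parameters

| name | unit | default | role |
|---|---|---|---|
| `sigma_min` | m | 100 | variance floor / minimum bandwidth `h_min`; choose ≈ habitat grain; larger for group centroids tracked via one member |
| `D` | m²/min | estimated | diffusion coefficient; "estimate" fits it from the track's own triplets |
| `T_max` | min | 180 | maximum recording interval warranting constant within-bridge drift; set from the serial-correlation horizon of the species/schedule |
| `tau` | min | largest value satisfying the spacing constraint | interpolation time constant; smaller = finer time discretization |
| `L_min` | m | 0 | minimum segment length; short active segments are dropped, or kept with `D = 0` for near-immobile foragers |
| `variance_mode` | – | constant_weight | "4a" constant floor vs "4b" merging |
| `cell_size` | m | `sigma_min/2` | UD grid resolution |
| `margin_factor` | – | 4 | grid margin in multiples of `h_max` |

Units are metres and minutes throughout; timestamps are converted to
minutes on ingest and coordinates must already be planar metres.

## Synthetic data

The generator produces discrete-step walks with constant step length
`s·Δt` and von Mises headings; the distribution family is a choice (the
bridge theory constrains only the mean cosine `c`), with the concentration
`κ` solved numerically from `c = I₁(κ)/I₀(κ)`. Walk types: `brownian`
(uniform headings), `brw` (absolute headings around `φ`; drift `v = s·c`),
`crw` (turning angles around 0), `bcrw` (headings around a weighted
compromise between `φ` and the previous heading). GPS subsampling keeps one
fix per `T_R`, attaches per-interval activity (constant or alternating
active/rest blocks), and drops interior fixes independently to create the
doubled intervals real collars produce (the study system recorded 0.3%
60-min gaps at a 30-min schedule). The isotropically equivalent diffusion
coefficient of a constant-step walk, `D = s²Δt(1 − c²)/4`, is the ground
truth used in recovery tests.

Defaults mirror the study conditions: 30-min fixes, `T_max = 180` min,
`σ_min = 100` m, buffalo-scale speeds (metres per minute) and `D` of a few
hundred m²/min.

What the generator does *not* emulate: speed variability (step lengths are
constant, so anisotropy effects never arise), attraction to a home-range
centre, habitat-driven behaviour beyond a per-habitat `(s, c)` override on
a raster, tortuosity within a recording interval beyond what the walk type
implies, and GPS *positional* error (the σ_min floor is a behavioural, not
a device, variance). Passing recovery tests therefore shows the estimators
are consistent for the model class they assume, not that real tracks meet
those assumptions.

## Numerical choices

- **Quadrature oracle.** The time integral of the bridge density uses
  composite midpoint quadrature (default 64 nodes): midpoint avoids the
  `t = 0, T` endpoints where the movement variance vanishes and the
  density would degenerate without the σ_min floor.
- **Kernel truncation.** Gaussians are cut at 4 bandwidths in gridded
  computation (< 1e-4 relative mass loss each) and the raster is
  renormalized to unit mass, so truncation and off-grid tails cannot bias
  isopleths.
- **Junction de-duplication.** A flat equal-weight re-indexing of per-
  segment locations would count each shared junction twice. Each included
  segment contributes `m = 0 … n_i − 1`; the terminal relocation of every
  maximal run of contiguous included segments is appended once. This
  preserves the proportionality of location counts to activity time
  exactly. Recorded fixes touched only by excluded segments still enter
  once with bandwidth `h_min`, which makes the estimator degrade to a
  fixed-bandwidth location KDE when every segment exceeds `T_max`.
- **Rounding and ties.** `n_i` uses round-half-away-from-zero (platform-
  independent), with minimum 1. Isopleths rank cells by density with ties
  broken by row-major index; a cell is inside level `p` when the cumulative
  mass up to and including it is ≤ `p/100`. Areas are cell counts × cell
  area, not contoured polygons.
- **Spacing constraint.** Interpolated points must be spaced below
  `2 h_min` along the chord (`h_min > 0.5 τ L_i/T_i`); planning fails with
  a message rather than producing a beaded UD. The default `τ` is the
  largest compliant value, capped at 1000 intervals per segment.
- **Degenerate inputs.** Zero-length segments are legal (their kernels
  stack at a point); fully resting segments are excluded as `resting` but
  their endpoints still contribute; `D = 0` yields a constant-bandwidth
  schedule; an estimation with zero retained couples returns an undefined-
  flagged result instead of raising mid-pipeline.
- **Rejection-sampled ensembles.** Endpoint-conditioned ensembles accept
  walks ending within a tolerance of the target and re-pin the deviation
  profile on each path's own endpoint, which removes the bias the
  tolerance would otherwise introduce; the run aborts with guidance when
  the acceptance rate falls below 1e-5.

## Design decisions taken where the method is open

- The estimator aggregates per-couple (and per-segment) unbiased ratios by
  their mean; the pooled ratio-of-sums variant is available
  (`aggregation="pooled"`) for sensitivity checks. With a regular fix
  schedule the two coincide.
- "Fully encompassed in habitat H" (for `D_H` and drift speeds) means both
  endpoints and chord samples every `sample_step` metres (default half the
  raster cell) carry code H — deterministic and resolution-aware.
- The applicability bound of the merging variance mode is taken as
  `D > 2σ_min²/T_max`, the unique value keeping its time increment
  positive.
- The 50-m-type length filter removes the segment's activity time from all
  downstream sums (as the `T_max` filter does) rather than re-attributing
  it; the removed total is logged and reported.
- Stationary-period detection is deliberately manual: the sliding-window
  mean/variance series is emitted for visual delineation, with half-open
  windows and population variance for determinism.
- The sklearn estimator surface (`BRBDensity`, `DiffusionEstimator`,
  `DriftSpeedEstimator`) wraps the functional core so parameter sweeps and
  cloning compose with standard tooling.

## Problem sizes

The test suite and the acceptance script size their simulations to keep
estimates statistically sharp while staying quick: diffusion recovery uses
a 120 000-step walk (~2400 retained couples, SE ≈ 2% of D), drift recovery
500 thirty-minute segments, conditioned ensembles 2000 accepted paths, and
oracle comparisons single bridges on `σ_min/4` grids. The whole suite runs
in well under a minute on one core.

## Known limitations

- No boundary management: kernels spill into physically inaccessible areas
  adjacent to the track.
- Anisotropic bridges and GPS-noise variance models are out of scope by
  design; σ_min is the only variance floor.
- Isopleth areas are cell-counted, so they depend (weakly) on grid
  resolution; printed normalized preferences computed from rounded
  percentages will not reproduce exactly.
- Habitat preference output is descriptive — no compositional tests or
  confidence intervals on selection ratios.
- `D_H` estimates in fragmented habitats rest on few couples; the tables
  always carry the sample sizes so they can be read with due caution.
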