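# Methods

This note documents the models, conventions, defaults, and design choices
behind `nedyn`, and what the synthetic-data validation does and does not
establish about real data.

## Conventions

Pixel coordinates are 0-based, x to the right, y down, with pixel centers on
integer coordinates; all physical conversions multiply by `pixel_size_um`.
Image stacks are carried as `(channel, time, z, y, x)` arrays with explicit
calibration; calibration precedence is explicit override > file metadata >
error (camera pixel sizes are instrument-specific and are never guessed).
Contours and membrane traces travel as a flat CSV point-list schema
(`object_id, slice_or_frame, vertex_index, x, y, closed_flag[, units]`);
closed polygons store the first vertex once, closure being implicit.
Tool-native trace formats (ROI snakes, tomogram model files) are not parsed;
converting them to the CSV schema is user-side.

## Nuclear import

The per-frame metric is `((N − bg)/(C − bg)) · area`, where `N` is the mean
reporter intensity inside the nucleus, `C` the mean of a 20×20 px box inside
the embryo, and `bg` the mean of a 50×50 px box in a vacant area (camera
offset). The ratio is invariant to additive camera offset and to uniform
multiplicative gain; the area factor compensates for nuclear-size
differences between conditions. Nuclear area is physical (µm²) by default —
values then compare across calibrations — with the pixel-area variant behind
a flag; the bare ratio is always reported alongside.

The manual chromatin tracing of the original protocol is replaced by a
reproducible global threshold (Otsu by default) on the chromatin channel
with largest-connected-component selection (components under `min_area_px`
removed); a user-supplied polygon overrides segmentation. Per frame, the
analysis runs on max-intensity z-projections. Isolated segmentation failures
become NaN frames; more than 50% failures abort the trace. Times are
`(frame − anchor_frame) · time_step` for a named anchor event.

**Onset detection** is a baseline-threshold rule: onset is the first time
the signal exceeds `mean + k·sd` of the first `baseline_n` points for
`persistence` consecutive frames (defaults 3, 3, 2). It operates on the bare
N/C ratio by default rather than the area-scaled value: nuclear area grows
throughout expansion, so the area-scaled metric drifts upward before any
import and a baseline threshold would fire on growth, not transport
(`signal="nc_value"` selects the scaled metric anyway). The rule is this
package's operational definition — onset is reported in the source study
without a stated criterion — and all three parameters are exposed.

**Normalized differences.** Traces on a common time grid are min-max
rescaled to [0, 1], averaged pointwise, and the first differences of the
average over consecutive intervals returned; a constant trace is an error,
and NaN frames propagate as NaN differences.

## FRAP

Raw series are normalized to the mean of the prebleach frames; t = 0 is the
first post-bleach frame. The recovery model is the printed single
exponential `f(t) = A·(1 − e^(−τt))`, which forces `f(0) = 0` (complete
bleach); an optional constant-offset variant (`include_offset=True`) absorbs
incomplete bleaching in real data. Fitting is bounded nonlinear least
squares with `A ∈ [0, 1.5]` — the bound sits above 1 so noise near `A ≈ 1`
is not clipped at a hard physical limit (fits with `A > 1` are flagged) —
and `τ > 0`. Initialization: `A₀` = last observed value (clipped), `τ₀` =
1/median(t); τ is multistarted over five decades and the lowest-RSS
converged solution wins. Reported: `A`, `τ`, `T½ = ln 2/τ`, `1 − A`, RSS,
and standard errors from the fit covariance. Replicates are fitted per curve
and then averaged (mean ± sample SD over converged fits, non-converged
counted and excluded) rather than fitting an averaged curve.

**Oracle validation.** The suite checks the optimizer against an exhaustive
200×200 grid search (A over the fit bounds, τ log-spaced over the same five
decades the multistart covers). Two regimes matter. Where the data identify
the parameters well (e.g. A = 0.47, τ = 0.03 s⁻¹ at 5% noise, 60 frames),
the fitted parameters agree with the grid argmin to within one grid cell.
Where the recovery is slow and shallow (A = 0.2, τ = 0.01 s⁻¹), the relative
standard error on τ reaches ~25%: the RSS valley floor spans several grid
cells and the discrete argmin wanders along the A–τ correlation valley, so
per-cell agreement is not a meaningful test there; instead the suite asserts
RSS dominance (the fitted RSS never exceeds the grid minimum) across all
truth points. Parameter-recovery simulations (100 curves per truth point at
5% noise) require median |Â − A| < 0.05 and that the estimated condition
ordering reproduces the truth ordering.

## Morphometry

* `measure_diameter`: threshold → binary → largest component → equivalent
  diameter `2·√(area/π)`; sphere surface area `4πr²` and volume `(4/3)πr³`
  follow exactly. (`4πr²` is the standard sphere surface area consistent
  with the adjacent volume formula.)
* `polygon_area`: shoelace formula with absolute value (orientation
  independent); self-intersecting polygons are rejected (validity via
  shapely, area computed here).
* `contour_volume`: Σ slice area × slice spacing. Spacing defaults to
  0.1625 µm, the isotropic light-sheet sampling, and is a parameter. There
  is deliberately no partial-slice end-cap correction — the plain Riemann
  sum matches the original protocol, and the <10% sphericity tolerance
  absorbs the discretization error (0.022% for an ideal radius-4 µm sphere
  traced as 256-gons at 0.1625 µm).
* `theoretical_volume`: the widest slice is the one of largest **area**
  (the alternative reading, largest linear extent, is less robust to
  tracing noise and inconsistent with the area-based diameter used
  elsewhere); `r = √(max area/π)` and `V = (4/3)πr³`.
* `sphericity_check`: relative deviation `|V_int − V_theo|/V_theo`, flagged
  when ≤ 0.10. An ideal sphere passes at ≪1%; a 2:1 prolate ellipsoid
  deviates by ~100% and fails, so the flag separates the two regimes with a
  wide margin.
* `growth_rate`: OLS slope of volume vs time (µm³/s) with intercept, R²,
  and the slope's standard error.

## Line scans

Sampling steps 1 pixel along the line with bilinear interpolation, averaging
`width_px` (default 3, odd) perpendicular offsets; the whole band must stay
inside the image. The two printed recipes are kept as distinct presets
rather than merged: `twocell` (10 µm line, perpendicular redraw averaged,
background = mean of the first and last two points) and `if` (5 µm line,
max-normalization, NE:cytoplasm and NE:nucleoplasm ratios against the first
and last five values, the line oriented cytoplasm → nucleoplasm). The "NE
value" in the ratios is the profile maximum — the only feature the profile
marks. Ratios are computed on background-corrected, max-normalized values
by default; correction can be skipped by not applying it, since the
operations compose explicitly. `background_correct` then `normalize_max` is
invariant to affine intensity maps `a·I + b` (a > 0) of the source image.

## Membrane gaps and hole density

Traces are 2-D polylines per tomogram slice, in nm — the same information
the visual scoring used; 3-D mesh analysis is out of scope. Gap candidates
are pairs of chain endpoints that are mutually nearest and within
`pairing_max_nm` (default 300 nm); endpoints of the same chain are never
paired, since a straight open chain shorter than the pairing radius would
otherwise pair with itself (cost: a single nearly-closed loop's gap is not
detected — trace such membranes as two chains). Unpaired endpoints (edges of
large ruptures) are reported separately.

The three acceptance criteria: (1) width — endpoint distance — strictly
< 100 nm, so exactly 100 nm is rejected; (2) taper: the membrane edges
narrow to a point. A single polyline cannot show inner/outer membrane
fusion, so taper is operationalized per side as the maximum perpendicular
spread of the last 5 vertices about the edge's terminal direction being
≤ `taper_max_nm` (default 20 nm) — straight, converging edges pass, blunt
hooks and folds fail; (3) flanks: continuous membrane arc length
≥ `flank_min_nm` (default 100 nm, the same length scale as the hole
criterion) on both sides. All thresholds are exposed parameters. Densities
are reported per region (count/area), as the mean of per-region densities,
and pooled (Σ counts/Σ areas); the two summaries coincide exactly when
region areas are equal and are reported side by side because either reading
of an "average density" is defensible.

## Tabular assays

Lethality pools the scoring windows per worm: lethality =
unhatched/(hatched + unhatched), brood = total; worms with zero scored
embryos are excluded with a warning; condition summaries give mean ± sample
SD, range, n worms and n embryos. ΔΔCt averages technical replicates per
sample first (standard practice), takes `ΔCt = Ct_target − Ct_reference`
per sample, `ΔΔCt` against the mean control ΔCt per gene, and
`fold = 2^(−ΔΔCt)`; plate offsets cancel exactly in ΔCt. Fold changes are
summarized by arithmetic mean ± SD over biological replicates, with a
geometric-mean (log-scale) variant behind a flag. The reference gene is a
required argument with no default, because housekeeping-gene choice is a
study decision, not a package decision. No amplification-efficiency
correction is applied.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their parameters (seed included) and
use the acquisition geometry of the assays they stand in for: 20 s frame
intervals with five z-slices at 2 µm for time lapses, 10 s FRAP intervals
with three prebleach frames, 0.1625 µm isotropic contour spacing. Import
kinetics use a saturating exponential `C·F·(1 − e^(−k_in t))` for nuclear
excess intensity (defaults k_in = 0.02 s⁻¹, plateau factor F = 3, radius
1 µm growing at 0.002 µm/s) — the simplest model with a closed form for
round-trip testing; the analysis stages never assume it. Noise is additive
Gaussian clipped at zero (default 2% of the cytoplasmic signal for images,
sd 0.05 for normalized FRAP).

Not emulated: optical blur (no PSF), Poisson photon statistics, acquisition
photobleaching, camera gain structure, nuclear movement, neighboring
nuclei, or tracing irregularity beyond bounded radial jitter. Passing the
round-trip suites therefore establishes that the estimators are correct and
stable under idealized imaging — it does not establish segmentation
robustness against real microscopy artifacts, which must be judged per
dataset (the manual-ROI override exists for that reason).

## Numerical notes and degenerate inputs

Constant frames, empty masks, zero prebleach means, all-zero profiles,
self-intersecting polygons, regions outside the frame, cytoplasm ≤
background, and too-short traces all raise typed exceptions
(`nedyn.errors`) rather than producing numbers. Sphere contour slices sit
at `z = k·z_step` strictly inside `(−r, r)`, so no slice is tangent.
`t_half·τ = ln 2` holds exactly by construction. CSV round trips preserve
coordinates bit-exactly (full-precision float formatting) and TIFF round
trips preserve pixels and calibration exactly.
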