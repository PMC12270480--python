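# Methods

This note documents the models behind `tunnelvision`, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## 1. Fisheye scene model and analytic flow oracle

The scene camera is an ideal **equidistant fisheye** (`ρ = f·θ`, with `f`
chosen so the configured field of view — default 185° — fills the image
circle).  The real lens's projection is undocumented; equidistant is the
simplest model with an exact closed-form flow field, and every quantitative
statement about rendered scenes is made relative to this model, not to any
physical lens.

The camera translates along its optical axis, so the focus of expansion
(FOE) is pinned to the image centre; no FOE estimation is performed
anywhere.  Scenes are unions of infinite textured planes (floor, ceiling,
side walls, end wall) at configurable perpendicular distances.  For a
pixel whose ray meets a plane at perpendicular distance `d` from the
camera path and eccentricity `θ`, the translational image motion is

    ω = v · sin²θ / d   [rad/s],   pixel speed = f_px · ω / fps,

directed exactly radially outward.  `analytic_translational_flow` /
`analytic_flow_map` evaluate this in closed form and serve as the oracle
for the whole flow pipeline; renderer and oracle share one geometry module,
and an *independent* check (sub-pixel SSD tracking of rendered texture,
`tests/test_synthetic_scene.py`) confirms the rendered motion matches the
closed form within 10% for θ ∈ [20°, 80°].

Textures are procedural (band-limited sinusoids, smooth checkers, seeded
C¹ value noise); frames are averaged over a 2×2 sub-pixel grid (4×
supersampling) to suppress spatial aliasing.  Rendering is bit-deterministic
given the spec (all randomness is a pure function of the seed).

**Scaled-up camera speeds.**  The field rig moved at 12 mm/s (the
`SceneSpec` default).  At desk-scale image sizes (160–200 px across) that
produces ~0.02 px/frame of motion, below any dense estimator's noise
floor; flow-validation scenes therefore use faster camera speeds
(~600 mm/s at the same geometry), putting displacements in the 0.5–2
px/frame regime dense estimators are designed for.  Only `v/fps` is
rescaled — the geometry, and hence the *relative* quadrant structure, is
unchanged — and linearity of the quadrant means in `v` is itself a tested
invariant (doubling the speed doubles every quadrant mean within 10%).

## 2. Dense flow estimation and the translational filter

The estimator is pluggable behind a fixed contract (two frames in, per-pixel
`(u, v)` px/frame out, feature motion from first to second frame).  The
default is scikit-image's **iterative Lucas–Kanade** (`radius=5`,
`gaussian=False`), selected by diagnosing per-radius accuracy against the
analytic oracle; TV-L1 is available as `FlowEstimator("tvl1")`.  Estimator
name and parameters are recorded in every output's metadata.

The **translational filter** keeps vectors whose direction deviates from
the outward radial direction by at most `angle_tol` (default 30°; the
appropriate tolerance is not derivable from first principles, so it is
exposed and recorded).  Pixels within 5 px of the FOE are zeroed (radial
direction undefined).  Rejected vectors count as **zeros** in the temporal
mean, so the map is the mean translational magnitude over the whole video;
`include_rejected_as_zero=False` switches to averaging only over surviving
frame pairs.

**Quadrant pooling.**  The four 90° sectors are bounded by the ±45°
diagonals (half-open, angles from the +x image axis, dorsal = up =
decreasing row) and partition the image circle exactly.  For natural-scene
style analyses the two lateral sectors can be pooled area-weighted; tunnel
analyses keep them separate.  `scene_flow_summary` excludes an outer
annulus of 8 px (≈ the estimator window) from pooling: window-based
estimators are invalid where their support crosses the synthetic image
circle's hard boundary into the uniform background.  Real fisheye videos
have no such boundary; the margin is a synthetic-world artefact, applied
identically to estimated and analytic maps wherever the two are compared.
Temporal averaging happens before quadrant pooling; since both operations
are means over fixed index sets, the opposite order gives identical values.

## 3. Edge scoring

Prewitt gradients use kernels normalised so an intensity step of amplitude
`a` has gradient magnitude exactly `a`; thresholds therefore read directly
on the [0, 1] intensity range.  Thinning is non-maximum suppression along
the quantised gradient direction.  Scores are closed over
`{0} ∪ thresholds` per frame by construction; per-video maps are temporal
means.  The default ladder is 0.01, 0.025, 0.05, 0.1, 0.5.

## 4. Tunnel, trajectories and silhouette videos

Tunnel frame: `x ∈ [0, 1000]` mm from the entrance, `y ∈ [−150, 150]` mm
signed from the midline, `z ∈ [0, 300]` mm above the floor.  Trajectory
regimes (straight, offset, diagonal cross over the central third,
oscillating, linear ramp) are deterministic profiles plus seeded Gaussian
positional noise.  Default traversal speed is 400 mm/s — a typical tunnel
flight speed, and slow enough that consecutive silhouettes overlap, which
the frame-differencing detector requires for sub-silhouette positional
accuracy.

The bottom camera (640 × 480 px at 50 fps, 1.5 m below the tunnel) maps
positions with a fixed per-axis linear calibration; only the silhouette
*size* carries perspective, shrinking as `depth / (depth + z)` (camera
below: larger area = lower flight).  The default silhouette radius is 9 px
at floor level (~a 30 mm moth at 0.6 px/mm).

## 5. Tracking

Detection: absolute frame difference → threshold (default 0.08 of the
intensity range) → 3×3 binary closing (joins the two crescents of the
silhouettes' symmetric difference, which may otherwise touch only
diagonally) → 8-connected labelling → largest component with ≥ 20 px² of
*raw* above-threshold pixels.  Area and the unweighted centroid are
computed from the raw pixels only, so the closing never inflates the area;
equal-area ties break on the smaller bounding-box top row.  The threshold
and minimum area are pipeline choices (robust on the synthetic renders),
not reconstructions of any historical setting, and both are exposed.

**Half-frame timing.**  The symmetric difference of two congruent
silhouettes is point-symmetric about the midpoint of the two positions, so
a detection from the pair (t−1, t) measures the position at time t − ½.
`assemble_track` linearly resamples the half-frame centroid series onto
integer frame times — exact for locally linear motion, and an implicit
one-frame smoother of positional jitter (visible as a lower
lateral-movement proportion for very noisy tracks).  Gaps of up to
`max_gap` frames are interpolated and flagged; longer gaps split the
stream into candidate tracks.  Area values get a 5-frame rolling median to
suppress segmentation jitter.

At the default speed the detection area is the symmetric-difference count
(roughly twice the silhouette minus overlap); at speeds where consecutive
silhouettes no longer overlap the detection is a full clean silhouette, as
in real videos of fast-flying animals — the area–height fidelity check
uses such a flight.

The completeness filter accepts tracks spanning from below the entry
margin (100 mm) to beyond the exit margin, with no backward excursion over
50 mm; reverse traversals are x-mirrored so accepted tracks always run
0 → 1000 mm.  A "no landing" proxy is implicit in this monotonicity rule.

## 6. Flight metrics

All metrics are computed on the central 80 cm (`x ∈ [100, 900]` mm).
Medians use the midpoint convention.  Speed uses 2-D (x, y) displacement —
the bottom camera cannot see height.  Interpolated frames are included in
the speed median (their chord speeds are unbiased for linear motion).
Degenerate steps in the lateral-movement proportion: frames with both
|Δx| and |Δy| < 0.1 mm are hovering and skipped; |Δx| < 0.1 mm with real
lateral motion contributes a capped ratio of 100, keeping the median
finite yet monotone in lateral activity.  The cross-index windows use the
**median** (consistent with the other statistics; the window statistic is
switchable to the mean), and its sign convention is exit-window minus
entry-window, so a positive index means net movement toward +y during the
traversal.

## 7. Statistics

- **Gate:** Shapiro–Wilk on pooled within-group residuals at α = 0.05;
  parametric iff p ≥ α; constant-valued groups force the nonparametric
  path.
- **Parametric path:** one-way ANOVA; Tukey–Kramer pairwise p-values from
  the studentised range with unequal-n standard errors.
- **Nonparametric path:** Kruskal–Wallis; the "Tukey-corrected" post hoc is
  the Tukey-type (Nemenyi) comparison on mean ranks via the studentised
  range with ∞ df and the usual tie correction — the standard reading of
  that phrase in common statistics toolboxes.
- **Letters:** insert-and-absorb compact letter display; equals the maximal
  cliques of the non-significance graph (verified by brute force in tests)
  and is invariant to input order via canonical sorting.
- **Brown–Forsythe:** pairwise Levene-with-median tests, reported
  *uncorrected* by default (a Holm flag is available); two identical
  samples define p = 1.
- **Mixed model:** `magnitude ~ habitat × quadrant + (1 | scene)` via
  statsmodels MixedLM, fitted by **ML, not REML**, so AIC and deviance are
  comparable across fixed-effect structures; the full model is flagged as
  preferred only if it attains both the lowest AIC and the lowest deviance
  against the null and both single-factor models.  The fit is cross-checked
  against R's lme4 (ML) in the test suite (log-likelihood and AIC agree to
  0.01).  Singular fits (scene variance → 0) are retained and flagged.
- **Contrasts:** marginal means over the cell grid with equal weights;
  Tukey adjustment per factor family via the studentised range.  Degrees of
  freedom use a **containment-style** approximation (habitat, a
  between-scene factor: `n_scenes − n_habitats`; quadrant, within-scene:
  `(n_scenes − n_habitats) · (n_quadrants − 1)`), because no installed
  library provides Satterthwaite df for this model; containment is the
  conservative classical split-plot assignment.

## 8. What the synthetic world does not emulate

Rendered scenes are planes with procedural textures: no photorealistic
habitats, no depth discontinuity statistics of real vegetation, no
exposure/rolling-shutter effects, no camera shake (and hence no need for
the stabilisation chain real footage requires).  Silhouette videos contain
a single rigid ellipse: no wing-beat area fluctuation, posture, roll/pitch
or motion blur — precisely the confounds that make the real area proxy
approximate.  A green test therefore establishes that the *algorithms*
recover what the stated world contains, not that real recordings would be
this clean.  Statistically, simulated tables are exactly the additive
mixed model; calibration results transfer to real data only insofar as the
model holds.

## 9. Pipeline and file conventions

Configs are YAML/plain dicts validated against a documented key set before
any stage runs; unknown keys, malformed trajectory/scene fields, and
unregistered condition ids fail fast.  Runs are idempotent per seed, reuse
existing stage outputs unless forced, and record every written file in a
JSON manifest (config hash, seed, stages, failure point).  All CSVs are
comma-separated UTF-8 with a header row.

Data dictionary (CSV columns):

- `tracks.csv`: `frame` (index at 50 fps), `x_mm`, `y_mm` (tunnel frame),
  `area_px2` (silhouette-difference area), `interpolated` (bool),
  `condition_id`, `flight` (replicate index).
- `metrics.csv`: `condition_id`, `median_lateral_position_mm`,
  `median_speed_mm_s`, `lateral_movement_proportion`, `cross_index_mm`,
  `height_proxy_px2`, `n_frames`, `flight`.
- `flow_quadrants.csv` / `edge_quadrants.csv`: `scene_id`, `habitat`,
  `spec_hash`, `{dorsal,ventral,left,right}_mean`,
  `lateral_combined_mean` (area-weighted pooled lateral sectors).
- `stats_omnibus.csv`: `response`, `test`, `statistic`, `p`, `alpha`,
  `choice` (gate outcome); `stats_pairwise.csv`: square p matrix;
  `stats_letters.csv`: compact letters for the omnibus family
  (`letters`) and the Brown–Forsythe family (`bf_letters`).
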