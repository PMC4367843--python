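# Methods

## The measurement and its models

A capillary break-up extensional rheometry (CaBER) test stretches a small
liquid bridge between two platens (here 1.2 mm diameter, initial gap
g₀ ≈ 0.3–0.7 mm, final gap g_f ≈ 1–2 mm, sample volume π r² g₀ < 1 µL) and
records the thinning of the resulting filament with a high-speed camera
(5000 fps in the laboratory configuration, 500 fps in the portable field
configuration).  Time is zeroed at the instant the moving platen settles;
the mid-filament diameter at that instant is D₀.  The normalised diameter
d(t) = D/D₀ then follows, depending on the constitutive character of the
fluid,

* Newtonian: `d = 1 − (2X−1) α t / (3 η₀ D₀)`, with rupture at
  `t_F = 3 η₀ D₀ / (α (2X−1))`.  X corrects for the non-cylindrical
  filament shape: X = 1 (ideal cylinder) or X = 0.7127 (non-inertial
  smooth filament).  The fit uses X = 0.7127 by default for real
  filaments; X = 1 is used for the silicone-oil benchmark.
* UCM: `d = exp(−t/3λ)`.
* Giesekus: `(4a−3) ln[(d + B)/(1 + B)] − (2 D₀ η₀ / α λ_G)(d − 1) =
  t/λ_G`, with mobility group `B = 2 α λ_G a / (η₀ D₀)`.  The law is
  explicit in t and implicit in d; forward evaluation inverts it by Brent
  bracketing on d ∈ [10⁻⁶, 1] (tolerance 10⁻¹² in d).  Because the law
  never reaches d = 0 exactly unless 4a = 3, the time at d = 10⁻⁶ defines
  a numeric break-up horizon; evaluations beyond it return 0 with a status
  flag.  a = 0 gives B = 0 identically, so the UCM limit (a = 0, η₀ → 0)
  is exact; η₀ = 0 with a > 0 is rejected (the mobility group is singular
  there).  With 4a = 3 the law is exactly linear with slope −α/(2 η₀ D₀).

Supporting diagnostics: Bond number ρ g L²/α (gravity vs capillarity; the
operating envelope keeps Bo < 0.5, worst case ≈ 0.30), capillary length
√(α/ρg), Rayleigh time √(ρD₀³/8α), viscous time η₀D₀/2α, elastocapillary
number Ec = 2λα/(η₀D₀), and the Hencky strain ln(g/g₀) of the platen gap.

All internal quantities are SI; the CLI accepts mm/ms/mN-per-m suffixes
and converts at the boundary.

## Image analysis

The fluid appears dark on a light background (backlit silhouette); an
`--invert` option covers the opposite contrast.  Thresholding is Otsu by
default (inclusive on the dark class) or a fixed threshold (foreground
strictly below it).  Widths are per-row outer-edge extents — the span from
first to last foreground pixel — which is robust to interior intensity
dips.  No sub-pixel refinement is performed; widths are integer pixels
(extension point).

Because only one platen moves, the neck drifts axially and must be located
per frame: the minimum width strictly inside a platen margin (default 10%
of the gap at each end), with ties broken towards the centre of the
filament span.  Platen rows are identified as rows within 1 px of the
frame's maximum width; the gap is the run of rows between the two platen
blocks, and the pixel scale is calibrated as known platen diameter /
maximum silhouette width in a pre-stretch frame.

Motion stop is the first frame from which the tracked gap stays within
±2% of g_f onward (with at least 5 frames of confirmation; a bare 5-frame
window would fire spuriously at zero crossings of the overshoot
oscillation).  Break-up is the first frame with neck width below 2 px —
below that the measurement is quantisation-dominated.  A filament already
below threshold at motion stop raises a premature-break-up error (the
fluid was too inviscid for the stretch speed).  A frame's time is
frame_index × frame_interval.

## Fitting

* Newtonian: OLS of d against t (free intercept); slope s →
  η₀ = −(2X−1)α/(3D₀s).  R² in the ratio domain.
* UCM: OLS of ln d against t; slope s → λ = −1/(3s).  R² in the log
  domain (the domain of the regression); zero diameters are excluded with
  a warning.
* Giesekus: bounded nonlinear least squares of the time-domain residual
  t_model(dᵢ) − tᵢ.  Initialisation follows the regression heuristic that
  stabilises this fit: the Newtonian-fit viscosity is an upper bound for
  η₀ and 10% of it the starting value; the UCM-fit λ seeds λ_G; a starts
  at 0.1 within [0, 10].  R² is reported in the ratio domain via
  round-trip inversion so the three models are comparable.

Two numerical choices matter for the Giesekus fit and were made after
observing the objective geometry:

1. **Analytic Jacobian, near-machine step tolerance.**  The objective
   valley is extraordinarily flat when B is large (the log term is nearly
   linear in d); finite-difference trust-region iterations stall many
   orders of magnitude above the true minimum.  With the exact Jacobian
   the noiseless fit recovers generating parameters to machine precision.
2. **A profiled global search and a D₀ nuisance scale.**  Writing the
   model as `t = k[ln(d+B₀) − ln(c+B₀)] − C₀(d − c)` shows it is linear
   in (k, C₀) for fixed (B₀, c); those two are profiled out exactly on a
   grid over log B₀ refined by a simplex search, giving a start point
   immune to the sloppy valley.  The scale c (bounds ±3%) absorbs the
   quantisation error of the measured D₀ — one camera pixel on D₀
   rescales every ratio by ~1/D₀px, and the parameter surface is sloppy
   enough that this small systematic otherwise slides the optimum tens of
   percent along the valley.  c is reported in the result flags when it
   departs from 1.  The lower viscosity bound is 10⁻⁹ Pa s rather than 0
   (the mobility group is singular at zero).

Identifiability deserves emphasis: with ~1% diameter noise the three
Giesekus parameters are **not** individually identifiable — the η₀/a
direction collapses (η₀ runs to its lower bound), exactly the behaviour
seen when fitting stored, degraded pitcher fluids.  The fitted curve
remains an excellent description (R² ≥ 0.98); only the curve, λ from the
UCM fit, and trends should be quoted at that noise level.  The recovery
tests therefore assert parameter recovery only for noiseless data and
curve adequacy for noisy data.

The fit window runs from motion stop to the last positive diameter;
`min_diameter` (e.g. the 2 px equivalent) trims the quantisation-dominated
tail, and `exclude_terminal` drops t/t_F > 0.8 for fluids with a sharp
terminal regime.  Points rising more than 0.05 (ratio units) above the
running minimum are treated as unphysical recoil and excluded with a flag;
plateaus and noise wiggle are kept.  Surface tension is always a user
input, never fitted.  `compare_models` ranks the three fits by reported R²
and sets a "Newtonian adequate" flag when the Newtonian R² comes within
0.01 (configurable) of the best — the practical signal that a fluid has
lost its viscoelasticity.  The storage-decay operation fits
ln λ = ln λ₀ − k·day by OLS (first-order decay of elasticity with sample
age).

## Synthetic experiments

The generator makes every stage testable with no laboratory data.

* **Kinematics**: gap = g₀ + v·t during the ramp (default v = 75 mm/s,
  so the benchmark 0.7 → 1.9 mm stretch takes 16 ms), then
  g_f + A e^(−τ/t_d) sin(2πτ/T) with A = 5% of the stretch, t_d = 3 ms,
  T = 4 ms — a slight overshoot with fast damping, continuous at the ramp
  end.  The ground-truth settling frame is where the envelope falls
  within 2% of g_f.
* **Traces**: any law sampled at camera rate, truncated at the model
  break-up time, with seeded additive Gaussian diameter noise (default
  study condition: 1% of D₀) clipped at zero; ground truth keeps the
  noiseless series.
* **Rendering**: two platen slabs plus a filament silhouette whose width
  interpolates by a raised cosine (zero slope at the neck and at the
  platen contacts, so the drawn minimum equals the intended diameter even
  when the neck falls between pixel rows) from the platen-contact width —
  0.9× the platen diameter, keeping platen and fluid rows separable for
  gap tracking — down to the mid-diameter.  The neck sits at half the
  initial gap above the stationary platen, i.e. progressively nearer it
  as the bridge stretches, emulating single-moving-platen asymmetry.
  During the stretch the mid-diameter follows volume conservation,
  D(g) = 2r√(g₀/g); after settling it follows the chosen law.  After
  rupture the frames show two disjoint caps.  Pixel noise is seeded
  Gaussian (default sd 5 on 8-bit).  Ground truth is the drawn integer
  width per row — the renderer defines truth by construction, it is not a
  free-surface flow simulation, so imaging assertions can be exact.
* **Benchmark suite** (bit-reproducible from one seed): a Newtonian
  silicone oil (η₀ = 2.37 Pa s, α = 0.0159 N/m) at three initial
  diameters; UCM fluids with λ = 2.95/20.6/29.8 ms (fresh greenhouse
  pitcher fluids); a strongly elastic field-fluid regime (η₀ ≈ 25 Pa s,
  λ_G ≈ 620 ms, a = 0.2), rendered at the field camera's 500 fps; and the
  relaxation-time-versus-storage-day series of two pitcher fluids.  One
  experiment per constitutive regime is rendered to video; recording
  lengths (0.35 s, 0.30 s, 1.7 s) are chosen so rupture falls inside the
  recording.

What the generator does **not** emulate: free-surface Navier–Stokes
dynamics (the neck shape is a drawing rule, not physics), gravity sagging
(Bo « 1 in range), evaporation, beads-on-a-string morphology, illumination
gradients and motion blur.  Passing the round-trip tests therefore
demonstrates that the measurement chain is unbiased for silhouette-like
footage with these noise models, not that it is robust to every artefact
of real field video.

## Recovery performance (computed by the test suite)

With noiseless synthetic traces all parameter recoveries are exact to
≤ 0.1% (linear fits, machine precision) and ≤ 2% (Giesekus).  Through the
complete rendered-video loop (render → calibrate → track → extract → fit)
recovery is within 5% without pixel noise and 15% under the default noise,
for all three models.  Random-draw recovery tests sample the device's
target regime — mobility a ∈ [0.05, 0.45], Ec ≥ 2 — where the
Newtonian-fit viscosity genuinely bounds the true Giesekus η₀; at higher
mobility that bound can exclude the truth and the heuristic breaks down by
construction.

## Known limitations

* Integer-pixel widths limit D₀ to ±0.5 px; the Giesekus nuisance scale
  compensates statistically but sub-pixel edge localisation would be the
  proper fix.
* Giesekus parameters from noisy single traces should be treated as a
  curve description, not as three independent material constants.
* The gap tracker assumes both platen silhouettes are visible and wider
  than the fluid contact line; heavily wetted platens would violate this.
* The motion-stop detector needs the recording to continue a few frames
  past settling; very short recordings raise an error rather than guess.
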