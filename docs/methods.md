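# Methods

This note documents the models, estimators and numerical choices behind
`nemadef`, and what its synthetic benchmarks do and do not establish about
real microscopy data.

## Coordinate and angle conventions

Arrays are indexed `[row, col] = [y, x]` with the origin at the top-left
pixel center and y pointing **down** (TIFF raster order); angles are
measured from +x toward +y, i.e. clockwise on screen. Director angles Θ are
nematic, stored in [0, π); every angle difference is reduced into
(−π/2, π/2] before use. Positions in output tables are micrometres, frames
0-based, velocities µm/h. Nematic quantities are always averaged or
interpolated through the order-tensor components (cos 2Θ, sin 2Θ), never as
raw angles: the π-ambiguity makes angle means ill-defined.

## Director estimation (orientation)

The director is the eigenvector of the smallest eigenvalue of the smoothed
gradient structure tensor `J = G_{σw} * (∇I ∇Iᵀ)` with Gaussian-derivative
gradients (scale `gradient_sigma`, default 2 px) and a Gaussian smoothing
window (`window_sigma`, default 8 px). Gaussian derivatives rather than
finite differences keep the estimate rotation-robust; the defaults resolve
structure at the 27.8 µm defect-detection window when the pixel size is
~1.9 µm. Coherency `(λ₁−λ₂)/(λ₁+λ₂)` ∈ [0, 1] flags reliability; it is set
to 0 where the tensor trace vanishes (flat images). Coarse graining to a
PIV-resolution grid block-averages the coherency-weighted tensor; a block
of mutually orthogonal orientations therefore comes out with coherency ≈ 0
and a flagged angle, rather than a meaningless mean direction.

## PIV (flow)

Single-pass window PIV: 16 px interrogation windows with 50 % overlap
(grid step 8 px). Each first-frame window is located in the second frame by
normalized cross-correlation against a search region padded by half a
window per side; the integer peak is refined per axis by the three-point
Gaussian fit `δ = ½(ln c₋ − ln c₊)/(ln c₋ − 2 ln c₀ + ln c₊)`. Two guards
matter numerically:

- a peak at the theoretical NCC maximum (a perfect match, e.g. a pure
  integer shift of identical content) has zero width, so no subpixel
  refinement is applied there — integer displacements are then recovered
  exactly;
- a peak on the border of the search range is untrustworthy (the true peak
  may lie outside) and the node is masked. This is the usual situation at
  image boundaries when material enters or leaves the frame; boundary nodes
  of the vector grid are therefore the least reliable, and the synthetic
  benchmarks assert exactness on interior nodes.

Windows without texture (zero variance) are masked. Spurious vectors are
flagged by the normalized median test (3×3 neighborhood, threshold 2.0,
ε = 0.1 px — standard practice) and optionally replaced by the neighborhood
median while staying marked invalid. The single-pass scheme is valid for
displacements ≲ window/3 per frame pair, which covers monolayer speeds of
tens of µm/h at 15–30 min frame intervals and ~1.9 µm/px.

## Defect detection and measurement (defects)

The windowed nematic order parameter
`Q(Ω) = √(⟨cos 2Θ⟩² + ⟨sin 2Θ⟩²)`, computed as a sliding mean over an odd
pixel window matching Ω = 27.8 µm, is 1 for perfect alignment and drops
toward 0 at defect cores. Detection takes local minima below
`q_threshold = 0.5`, suppresses neighbors within `min_separation` (default
Ω, deepest minimum wins), refines each minimum by a per-axis parabolic fit,
and excludes a margin (largest loop radius + 1 px) at the field border.

Charge is the winding number: Θ is sampled at 72 points on a circular loop
(bilinearly, through the tensor components), successive nematic differences
are reduced into (−π/2, π/2], and their sum over the closed loop divided by
2π gives k. The raw value is snapped to the nearest multiple of ½ when
within 0.1; candidates that fail to snap to a non-zero half-integer on all
polled loops (radii 5, 8, 11 px, majority vote) are dropped and logged —
discrete fields near cores are noisy and a single loop radius is fragile.

The ±1/2 axis is measured from the same loop: around an isolated charge-k
defect the director follows `Θ(φ) = kφ + c`, so the circular mean of
`exp(2i(Θ − kφ))` estimates the offset c (mod π, which is exactly the
freedom the axis needs). For k = +1/2 the comet tail lies along `ψ = 2c`
(unique in [0, 2π)); for k = −1/2 the three symmetry axes are `2c/3 + n·2π/3`
and the canonical representative in [0, 2π/3) is reported. This
loop-residual estimator was chosen over the divergence-of-Q polarity
estimator because it reuses the winding-loop samples, handles both charges
uniformly, and is unbiased on the analytic one-defect solution; on
synthetic scenes with separations > 3Ω it recovers axes to < 0.5°.

## Synthetic scenes (synthetic)

Director fields use the one-elastic-constant solution `Θ = Σᵢ kᵢφᵢ + cᵢ` +
background. Each constant cᵢ compensates the background and the other
defects' phases at core i, but a superposed field carries only **one**
global phase: with several defects the individual axes cannot all be
prescribed independently. The generator therefore records the *realized*
axes (computed in closed form from the same constants) in the truth table;
for a single defect the requested axis is realized exactly. The sign
convention is calibrated once: `Θ = (φ + ψ)/2` puts the comet tail along ψ
(the director is radial at φ = ψ), and the tail is what `axis_angle` means
for +1/2 throughout the package.

Textures are line-integral convolutions: white noise is averaged along
streamlines of the (sign-disambiguated) director over ±`stripe_period` px
(default 24 px ≈ 45 µm, the long-axis scale of elongated myoblasts),
iterated twice and finished with an unsharp mask (σ = 2 px) that sharpens
across-streak structure. This model was chosen over drawing discrete cells
because its ground-truth structure tensor is the director by construction;
it reproduces the streaky anisotropy of phase-contrast monolayers but none
of their intensity nonuniformity, cell boundaries or debris. The benchmark
result (director recovered to < 5° RMS at coherency > 0.2) therefore bounds
estimator error on ideal texture, not segmentation robustness on real
images.

Flow fixtures are parametric, not active-gel solutions (the qualitative
flow structure is the modeled feature). The motile comet field derives from
the stream function `ψs = v₀ y' e^{−r/ℓ}` in the defect frame: divergence-
free, core velocity v₀ toward the tail, and a counter-rotating vortex pair
with vorticity antisymmetric about the axis. The stationary variant is zero
on the tail half-plane and points toward the core with magnitude
`v₀ e^{−r/ℓ}` on the head half-plane. Defaults v₀ = 20 µm/h, ℓ = 50–60 µm
match the measured flow scale around monolayer defects. Trajectories are
`start + v·t` plus isotropic Gaussian jitter; FA images are filled ellipses
of prescribed area/aspect/orientation, lightly smoothed (σ = 0.6 px) on a
Gaussian-noise background; nuclei are a homogeneous Poisson process with an
optional disc where the density is `fold × base`.

## Tracking and motility classes (tracking)

Linking is greedy mutual-nearest-neighbor between consecutive frames,
restricted to equal charge and displacement ≤ `max_disp_per_frame`
(default 30 µm); unlinked observations open new tracks and a missed frame
terminates a track (no gap closing). Global assignment was not used because
defect counts per field of view are small (≲ 10) and collisions rare; the
known failure mode is a swap when two same-charge defects cross within one
frame step. Backward tracking from a reference frame is the same operation
on the reversed frame order. Track speed is the mean of |Δr|/Δt after
optional box smoothing of positions (default 5 frames; the smoothing
suppresses the upward bias that localization jitter adds to path length).
Tracks are classified stationary when the mean speed is < 10 µm/h, motile
otherwise, and unclassified when observed for less than 2 h. Defect density
is the per-frame count (optionally one charge) divided by the field area in
mm².

## Defect-frame averaging (defect_frame)

Each +1/2 observation is resampled onto a grid spanning ±150 µm (default)
around the core, rotated by −ψ so the tail lies along +x: director angles
shift by −ψ after tensor resampling, velocity vectors rotate by −ψ,
out-of-field nodes are masked. Ensemble averaging is per node over unmasked
patches (tensor mean for the director; component mean for velocity), with a
minimum-count mask. The axial profile bins the x-component of velocity over
the band |y| ≤ 30 µm (default) with per-bin SEM; a band rather than the
full y-extent keeps the profile from diluting the core signature with
far-field flow. The contractility diagnosis averages v·x̂ over a core disc
(default 30 µm): toward the tail beyond a 0.5 µm/h noise floor =
contractile, toward the head = extensile, else indeterminate; the
counter-rotating vortex pair is reported as the correlation between the
vorticity field and its negated mirror about the axis. Cell-density maps
are sliding-window point counts per mm²; the head-density profile bins
nuclei positions along defect-frame x in the same band geometry.

## Focal adhesions (fa_morpho)

All images of a comparison set are histogram-equalized and thresholded at
one shared absolute level. The level defaults to Otsu computed on the
pooled **raw** intensities and carried into the equalized domain as the
corresponding quantile — equalization flattens the histogram, so Otsu run
after it would always split mid-range and flood sparse images with
background. A bimodality guard (foreground–background mean separation must
exceed twice the summed class SDs) returns an empty segmentation for
blob-free images instead of labeling noise specks. Components use
8-connectivity.

Area is pixel count × pixel_size²; perimeter uses the Crofton (4-direction)
estimator — naive boundary-pixel counting biases circularity above 1 for
small discs; with Crofton a digital disc of radius 10 px measures
circularity ≈ 0.94, converging to 1 from below as resolution grows, with a
documented headroom ε = 0.1 for discretization overshoot. Circularity is
`4π·area/perimeter²` and is scale-invariant; orientation comes from second
central moments, reported nematically in [0, π) in image coordinates. The
area filter keeps the open interval (1, 7) µm²: values exactly 1.0 or
7.0 µm² are excluded. Head/tail assignment splits the plane along the line
through the core perpendicular to the defect axis (head: defect-frame
x < 0) within a 150 µm radius. The head-vs-tail circularity comparison uses
a two-sided Mann–Whitney U test (circularity is bounded and non-Gaussian);
adhesions are pooled across fields of view, so the p-value treats
adhesions, not fields, as independent units — a caveat when adhesions
within one field are correlated. Orientation histograms are nematic, binned
over [−90°, 90°) relative to the defect axis.

## Pipeline, sizes and determinism

`run_pipeline` executes orientation → PIV → detection → tracking →
defect-frame averaging, writing CSVs with a fixed float format plus a JSON
config snapshot; identical config and seed reproduce byte-identical tables.
The CLI (`nemadef orient/piv/defects/track/fa/synth/run`) is a thin wrapper
over these functions. The benchmark suite uses 192–256 px scenes
(~360–475 µm at 1.856 µm/px), 50 random scenes for the detection round
trip, 6–8 patches for averaging ensembles and 40 replicates for the
Mann–Whitney power estimate — sizes at which every quantity is stable to
well inside its tolerance while the whole suite runs in tens of seconds.

## Known limitations

- The texture generator does not emulate intensity gradients, cell
  boundaries or imaging artifacts; real-image director estimation will be
  noisier than the synthetic benchmark indicates.
- Single-pass PIV has no window deformation or multi-grid refinement;
  displacements approaching window/3 per pair need a shorter frame
  interval.
- Track linking can swap crossing same-charge defects; no gap closing.
- Integer-charge (±1) defects are charged correctly by the winding number
  but have no axis measurement.
- Annihilation events end tracks but are not paired or detected as events.
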