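# Methods

This note documents the models implemented in `patchdyn`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Geometry and TIRF visibility

A cell is a spherocylinder of length L (pole to pole) and diameter
D_cell lying on the coverslip with its axis in the focal plane. A
surface point at angle φ from the bottom line sits at height
z = (D_cell/2)(1 − cos φ); under evanescent illumination with
penetration depth h (default 0.2 µm) it is *visible* when z ≤ h. The
visible fraction of the circumference is f = arccos(1 − 2h/D_cell)/π;
for D_cell = 0.89 µm and h = 0.2 µm, f = 0.314 — the bottom third of
the cell. The projected visible region is a band of half-width
w = sqrt(2Rh − h²) along the sidewall plus half-disk pole caps, total
area 2w(L − D_cell) + πw².

Excitation intensity decays as exp(−z/h), so a patch approaching the
edge of the visible band fades smoothly rather than disappearing at a
hard boundary. Both facts — geometric visibility and photometric decay
— are modelled explicitly and drive several of the limitations noted
below.

## Synthetic data

The generator produces what the analysis assumes about real recordings:

- **Directed tracks** move circumferentially at constant surface speed
  ν (default 0.055 µm/s): φ advances by 2νΔt/D_cell per frame, the
  projected lateral coordinate is y = (D_cell/2)·sin φ, the axial
  coordinate is constant. Apparent (projected) speed is ν·cos φ.
- **Random tracks** are Brownian walks on the unrolled surface
  (per-axis step variance 2DΔt, default D = 0.002 µm²/s), reflected
  axially at the cylinder ends and circumferentially at the visibility
  edge. The circumferential reflection stands in for the steady-state
  exchange of walkers across the band edge: in stationarity the flux
  out equals the flux in, so reflecting preserves the visible count
  without simulating the invisible two-thirds of the surface.
- **Confined tracks** are Brownian steps radially reflected at a disk
  of radius R (default 0.15 µm). The stationary distribution is uniform
  on the disk, giving a closed-form long-lag MSD plateau of exactly R²
  (0.0225 µm² — below the 0.05 µm² classification plateau). The
  discrete reflection is unbiased when the per-step σ is well below R;
  tests run in that regime.
- **Population composition.** The target instantaneous visible count is
  ρ × visible projected area (ρ default 2 µm⁻²), split among the modes
  by the configured fractions (default thirds). Directed tracks spend
  only f of each revolution in view and are therefore oversampled by
  1/f; counts use stochastic rounding so the expectation is exact.
  Patches are placed on the cylindrical sidewall only (no poles). A
  configured "unclassified" mass is not generated — unclassified is an
  analysis outcome, not a motion model.
- **Rendering.** Each visible spot is a 2-D Gaussian of width
  psf_sigma_um (default 0.08 µm ≈ 1.25 px, the diffraction limit for
  GFP at NA 1.49), amplitude scaled by exp(−z/h). A diffuse cell-body
  term (peak 40 photons over a 100-photon background) follows the
  bottom-surface height profile exp(−z(x, y)/h), so the body brightens
  toward the centreline and fades toward the cell edges with no
  artificial intensity step. Poisson shot noise is applied to all
  photon terms, then additive Gaussian read noise (σ = 3), then
  quantisation to uint16. With the default amplitude of 150 photons the
  peak SNR — peak / sqrt(total variance at the peak) — is ≈ 8 at the
  cell bottom, decaying with z.
- Track-level (non-movie) fixtures add Gaussian localisation noise
  (default σ = 20 nm) to ideal trajectories, separating tracking and
  classification error from detection error. `simulate_directed_track_planar`
  provides the straight-line constant-speed idealisation used for
  classifier calibration, where MSD = (νt)² exactly.

Identical configurations (including seed) produce byte-identical
movies and ground-truth tables.

**Not emulated:** photobleaching, blinking, patch assembly/disassembly
(tracks persist for the whole movie), 3-D PSF structure, stage drift,
EMCCD excess noise (gain is folded into one scale factor), motion blur
within the 100 ms exposure, and multi-cell fields of view. Passing
tests therefore demonstrate correctness of the analysis under these
idealisations, not robustness to every nuisance of real recordings.

## Detection

Per movie: a maximum-intensity projection (MIP) is thresholded to get
the cell contour; per frame: a difference-of-Gaussians band-pass
(σ₁ = 1 px, σ₂ = 4 px) is followed by watershed segmentation thresholded
at 4 standard deviations of the enhanced intensity with 1-s.d. splitting
steps (h-maxima markers: two touching maxima stay one object unless
separated by at least one further s.d.). Each catchment yields one
detection at its intensity-weighted centroid; detections outside the
1-px-dilated cell mask are discarded; ρ = mean per-frame count / area.

Numerical conventions and choices:

- **Threshold scale.** "Standard deviation of image intensity" is, by
  default, the robust s.d. (1.4826 × MAD) of the enhanced frame, which
  is insensitive to the bright spots themselves. Two alternatives are
  provided: the plain s.d., and a noise-propagation estimate (robust
  s.d. of raw adjacent-pixel differences × the DoG kernel norm). The
  latter is a true noise floor but lies below the residual band-pass
  response of the cell body — a rod 14 px wide is inside the DoG's
  pass band — and admits false positives along the cell, so it is not
  the default.
- **Segmentation.** The MIP of a spot movie is trimodal (background,
  cell body, spot streaks); a plain two-class Otsu often splits body
  from streaks instead of background from cell. The threshold is
  therefore the lowest cut of a three-class Otsu computed on a
  σ = 2 px smoothed copy and applied to the raw MIP (sharp contour; on
  a genuinely bimodal image this coincides with plain Otsu). The
  largest connected component is kept and holes are filled. Note the
  measured contour is the TIRF-visible band: its width underestimates
  D_cell (≈ 2w rather than D_cell), as it does in real TIRF data.
- **Cell dimensions.** Length is the pixel extent along the mask's
  principal axis. Width is the moment width sqrt(12·var⊥ + 1) px —
  exact for a filled rectangle and rotation-invariant, unlike
  edge-counting or discrete medial-axis estimates which carry ~6%
  lattice bias at 64 nm pixels.
- **Minimum region size** of 2 px: a diffraction-limited spot above
  threshold always spans several pixels; single-pixel excursions are
  noise. This keeps false positives on noise-only frames below
  0.1/frame at the 4-s.d. threshold.
- **Localisation.** Intensity-weighted centroid on the enhanced image
  (deterministic, fast; median error ≈ 0.2–0.3 px at SNR 8). An
  optional 2-D Gaussian least-squares refinement on the raw frame is
  provided but is not the default: on cells the curved body background
  biases the fit and it measured slightly *worse* than the centroid.
- Detection scoring against ground truth (in `detection_metrics`) is
  restricted to spots at least 5 px from their nearest visible
  neighbour — closer pairs merge by diffraction; two spots 2 px apart
  are one detection by design — and with effective SNR ≥ 6, since
  spots deep in the evanescent decay are "visible" geometrically but
  are not imaged at the movie's nominal SNR.

## Tracking

Detections in consecutive frames are linked by minimum-total-cost
bipartite assignment (Jonker–Volgenant via
`scipy.optimize.linear_sum_assignment` on the standard augmented
matrix): link cost = squared displacement, gated at 3 px; terminating or
starting a track costs gate². No gap closing, no merging, no splitting —
a missed detection ends the track. The test suite checks the assignment
against exhaustive enumeration of all gated partial matchings.

This linker deliberately replaces motion-model (Kalman) tracking: at
1 s intervals and ≤ 1 px/frame motion, position prediction is
second-order for *linking*. It is not second-order for *crossings*:
when a rotating patch passes within the gate of another patch, the
identities can swap, and the resulting mixed tracks are the main loss
channel for directed-fraction recovery (below).

## Motion classification

Per track of ≥ 5 points: the time-averaged MSD over all overlapping
pairs, lags 1 … ⌊7/8·(n − 1)⌋ frames. Two one-parameter models are
fitted through the origin — MSD = (νt)² on t² and MSD = 4Dt on t — and
R² is computed about the (weighted) mean, so it can be negative for
origin-constrained fits of flat profiles; that makes the 0.8 acceptance
threshold conservative. Class rule: directed if R²_dir ≥ 0.8 and
R²_dir ≥ R²_ran; random if R²_ran ≥ 0.8 and R²_ran > R²_dir;
constrained if both R² < 0.8 and max MSD < 0.05 µm²; unclassified
otherwise. Ties at equal R² go to directed (a deliberate, documented
orientation of the dominance rule).

Numerical choices:

- **Lag weighting.** Fits weight each lag by its overlapping-pair
  count (as in the widely used MSD-analysis toolboxes). The
  time-averaged MSD at lag n averages only N − n pairs and its variance
  grows steeply with n; with equal weights a handful of noisy long-lag
  points fake quadratic curvature and push the Brownian → directed
  misclassification above its calibrated level. Unweighted fits are
  available as an option (`weight_by_pairs=False`).
- **No intercept.** The fitted models carry no localisation-noise
  offset; an offset variant was evaluated and rejected because the
  extra parameter lets quadratic fits chase noisy Brownian curves.
- Negative fitted slopes clip ν or D to zero; R² is reported for the
  raw fit.
- The scale relations hold exactly: scaling coordinates by c scales ν
  by c and D by c² and leaves both R² unchanged (the 0.05 µm² plateau
  rule is intentionally absolute and breaks this symmetry).

The diffusion coefficient is also estimated from the pooled squared
displacements at lag 1: under 2-D diffusion they are exponential with
mean 4DΔt, so the maximum-likelihood estimate is mean(r²)/(4Δt); a
least-squares fit of the empirical CDF is provided as a cross-check.

## Per-cell statistics

Every detection carries its track's class (tracks < 5 points count as
unclassified); class shares are computed per frame and averaged over
frames with detections, so θ_d + θ_r + θ_c + θ_u = 1 by construction.
ρ_d = θ_d·ρ. Mean directed speed averages the fitted ν of directed
tracks with ≥ 4 steps and is optionally multiplied by the deprojection
factor φ_max/sin φ_max (≈ 1.18 for the default geometry): the MSD fit
measures the chord-projected speed, whose band average is
ν·sin φ_max/φ_max. Bootstrap standard errors resample whole tracks with
replacement (seeded); the estimator is calibrated against sd/√n on
i.i.d. data and scales as 1/√n.

**Known accuracy limits under the default study conditions** (measured
against ground truth by the acceptance suite): recovered ρ runs ≈ 10%
low — diffraction merges of close pairs plus sub-threshold spots near
the visibility edge — and θ̂_d recovers ≈ 0.25 against a simulated 1/3.
Pure single-pass directed tracks classify as directed essentially
always (R²_dir ≈ 0.99); the θ_d deficit comes from crossing-induced
identity swaps (mixed tracks classify as random/unclassified) and from
1–4-point stubs where a patch enters or leaves the visible band. Both
are consequences of the deliberately simple no-motion-model,
no-gap-closing tracker, not of the estimators.

## Growth models

With N_d directed patches per cell moving at ν over a generation τ
(an *input*, measured by bulk growth, never inferred from movies), the
patches sweep N_d·ν·τ of arc, i.e. FT = N_d·ν·τ/(π·D_cell) full turns.
The sidewall elongation per generation is L − D_cell, so the axial band
width inserted per turn is ω = (L − D_cell)/FT; integrating synthesis
over an exponential cell cycle gives ω = ln2/(τ·ν·ρ_d). Substituting
N_d = ρ_d·π·D_cell·(L − D_cell) makes the two identical up to the
factor ln 2 — asserted symbolically on random parameter sets, along
with invariance of FT and ω under consistent unit rescaling.

The cross-cell regression of (L − D_cell) on FT estimates ω as a slope.
The synthetic population generator mirrors the experimental design: two
growth conditions (poor/rich) with condition-specific generation times
(4050 s / 1350 s) and length distributions (2.2 ± 0.25 µm /
3.8 ± 0.4 µm — rapidly growing cells are roughly twice as long), patch
speed inversely proportional to generation time (ν = ln2/(ω·ρ_d·τ), the
speed-tracks-growth-rate regime), directed density 2/3 µm⁻², and 10%
relative scatter applied to the *measured elongation*, not to FT —
noise on the regressor would attenuate the slope (errors-in-variables),
which is a property of the generator, not the estimator. A scalar ω
yields one line across conditions (slope ≈ ω, r² > 0.9); a per-condition
ω mapping reproduces the contrasting regime in which each condition has
its own slope.

Whole-cell patch counts are extrapolated from TIRF counts by dividing
by the visible fraction f (capped at 1). Upshift time courses group
per-cell summaries by time label (mean ± SD per statistic, optional
normalisation to the pre-shift mean); instantaneous growth rate is the
sliding-window (default 3 points) slope of ln(area) versus time.

## Insertion lattice

The sacculus is abstracted to an axial sequence of circumferential
strands per layer; axial length is counted in peptide-bridge units
(strands − 1) and strand length, helical pitch, crosslink chemistry and
kinetics are out of scope. 3-for-1 (monolayer): one strand is replaced
by a triplet — per event, strands +2, length +2 bridges, released +1.
3-under-2 (multilayer): a triplet is hooked under two adjacent
unconsumed template strands of the stress-bearing innermost layer —
per event, length +1 bridge, no release; when the template layer is
fully consumed the outermost layer is shed (its strands counted as
released), the completed new layer becomes the template, and the cycle
restarts — the inside-to-outside maturation as a layer state machine.
A strand-conservation ledger (total = created − released) is asserted
after every event. Odd-sized template layers retire with one unpaired
strand, which is shed with its layer. Positions are chosen by a
sequential or seeded-random policy; replay is deterministic.

## Pipeline and reproducibility

`PipelineConfig` collects every tunable with the standard defaults
(σ₁ = 1 px, σ₂ = 4 px, 4 s.d./1 s.d. watershed, 3 px gate, ≥ 5 points to
classify, ≥ 4 steps for speed, R² 0.8, 0.05 µm² plateau, 7/8 lag rule,
64 nm pixels, 1 s frames, 0.2 µm penetration depth); configs round-trip
through YAML/JSON and reject unknown keys. Every stochastic component
takes a seed; fixed seeds give byte-identical movies and output tables.
Simulation panels in the test suite and acceptance script use 6–24
movies of a single 3.0 × 0.89 µm cell and 500 tracks per motion mode —
sizes at which the panel means are stable at the few-percent level
while the whole suite runs in well under a minute per component.
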