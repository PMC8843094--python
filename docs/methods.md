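# Methods

## Geometry and pattern synthesis

The rig sculpts light in 4D: a DMD at an image-conjugate plane sets the
lateral amplitude pattern `(x, y)` while scanning mirrors set the
illumination angle, parameterized by azimuth ϕSM and a fixed polar angle θ
(all beams lie on one cone; the spatial-frequency pair is
`(kx, ky) = tanθ·(cos ϕSM, sin ϕSM)`).

**Coordinate convention.** Sample frame in µm, right-handed, origin on the
optical axis at the native focal plane, +z pointing deeper into the sample
(away from the objective). The DMD grid is row-major and 0-based; pixel
`(row, col)` maps affinely to the sample plane with pitch `um_per_px`
and its center at `((col − (cols−1)/2)·um_per_px, (row − (rows−1)/2)·um_per_px)`.
Every export records this convention implicitly through the plan config.

**Ray model.** A DMD point at lateral position `p` illuminates
`p + z·tanθ·(cos ϕSM, sin ϕSM)` at depth z. Back-projection of a target
`(x, y, Δz)` therefore places its aperture at
`(x, y) − Δz·tanθ·(cos ϕSM, sin ϕSM)`: for a below-plane focus (Δz > 0) the
aperture sits at ϕDMD = ϕSM + π on its sweep circle, for an above-plane
focus at ϕDMD = ϕSM (negating Δz is the π-phase-shift case). The sweep
circle has diameter `D = 2|Δz|·tanθ/um_per_px` pixels. Sweep azimuths are
evenly spaced over [0, 2π) starting at ϕSM(0) = π, so the first frame of a
below-plane focus has its aperture at ϕDMD = 0, matching the hardware
worked example (−2 V on the x-galvo, 0 V on y, for a 2 V amplitude).

**Pixel membership.** A DMD mirror is ON iff its center lies inside an
aperture disk; boundary ties are ON; union semantics across overlapping
disks (overlaps are not double-counted — the mirrors are binary). Power
weighting scales the aperture radius by √factor (power ∝ area); the
unrounded radius is used for synthesis and simulation, the half-up-rounded
integer radius is reported for display. Radii below 1 px are rejected as
unrenderable.

**Ray pruning.** A beam is the capsule of the aperture's radius (in µm)
from the aperture at z = 0 to the target; it is removed when the capsule
intersects an exclusion sphere. Pruning all of a target's beams is an
error. Power re-balancing after pruning is off by default; when enabled the
survivors grow by √(n/n_remaining). The balance rule is this package's
choice — aperture area is the documented power control, but no
pruning-compensation rule is prescribed anywhere, so it is exposed as an
option rather than a default.

## Forward optics simulation

The simulator is purely geometric and incoherent: the opsin integrates over
timescales far longer than one frame, so the effective illumination is the
dwell-weighted sum of each frame's sheared mask,

    I(x, y, z) = Σ_f dwell_f · mask_f((x, y) − z·tanθ·(cos ϕSM_f, sin ϕSM_f)).

Masks are sampled bilinearly during the shear (continuous sub-voxel
translation); a nearest-neighbor mode exists for oracle comparisons.
Because shear is a per-plane translation, in loss-less mode (no blur,
lateral voxel pitch equal to the DMD pixel pitch, grid covering the sheared
masks) every z-plane's summed intensity equals Σ_f dwell_f·ON-area(mask_f)
to machine precision — the plane-energy invariant asserted in the tests.

Diffraction and tissue scattering are **not** modeled physically. A
`BlurModel` applies a lateral Gaussian of σ(z) = σ₀ + slope·depth to each
plane; this reproduces the qualitative broadening of foci with tissue depth
and gives beams the soft edges needed for meaningful axial-sectioning
curves, but it makes no quantitative claim about scattering physics
(no Monte-Carlo photon transport, no coherent propagation, no speckle).

**FWHM.** Measured between half-maximum crossings with linear
interpolation; plateaued maxima use the outermost crossings. Reaching the
half-maximum exactly counts as a crossing: the 2-beam axial profile's far
field is exactly half its peak (one of the two disks is always present), so
a strictly-below rule would make the 2-beam width undefined. A profile that
stays strictly above half-max raises an error — that is the single-beam
case, which has no axial sectioning. Consequence worth knowing: the 2-beam
FWHM is determined by where the inter-beam overlap numerically vanishes and
is therefore sensitive to the grid range and sampling phase; the n ≥ 4
widths are stable.

**Axial sectioning curve.** Rendered for a single centered target per beam
count with fixed θ and aperture and fixed *total* dwell (stim time divided
among frames). With hard-edged binary disks the max-intensity z-profile's
half-width is nearly independent of beam count (a k-of-n disk-coverage
argument gives 2r/(cosπ/n·tanθ)); the documented resolution gain with beam
count appears once beams have soft profiles, so the curve is computed with
the Gaussian blur enabled (default study condition: 6 px aperture,
σ₀ = 1.5 µm, θ = 0.35 rad). The curve reproduces the qualitative trend —
monotone non-increasing with diminishing increments, minor gains beyond
~10 angles — not any specific published numbers, since the underlying beam
profile of such simulations is not specified anywhere the package could
adopt it from.

**Misalignment.** A phase offset Δϕ between mask placement and galvo
azimuth moves each beam's landing point at the target plane along a chord
of the sweep circle: the focus becomes a ring of radius
`2·Δz·tanθ·sin(Δϕ/2)`, measured in the simulator as the intensity-weighted
mean radial distance at the target plane (matches the closed form to within
a voxel). An elliptical scan (y/x amplitude ratio a ≠ 1) focuses the x-beam
pair at Δz and the y-beam pair at Δz/a — astigmatism, detected as two
distinct on-axis intensity maxima.

## Control waveforms

`galvo_x(t) = A·cos ϕSM(t)`, `galvo_y(t) = A·sin ϕSM(t)` with ϕSM sweeping
one full cycle per epoch from the start phase π; the DMD trigger has one
rising edge per frame (n_angles uniformly spaced edges per epoch, 2 samples
high at 5 V); the laser gate holds its level during the epoch and is zero
outside. The volts↔θ calibration is a required user input (rig-specific;
linearity volts ∝ tanθ assumed). The command is a continuous sinusoid even
though the angle is conceptually constant per frame — per-frame sweep is
2π/n_angles over ~0.4 ms (4 ms / 10 angles; a "0.3 ms" per-beam figure
sometimes quoted for this configuration is inconsistent with 4/10 ms and the
duration/n_angles value is used) and the resulting angular smear is accepted;
a stepped mode emits piecewise-constant angles for worst-case analysis.
Default sample rate 250 kHz (multifunction-DAQ territory), with a floor of
20 samples per frame. Pulse trains place epoch onsets at i/rate; between
epochs the galvos hold their last angle, trigger and laser are low.

Scheduling: grid sites in raster order (x fastest); Poisson-disc ordering
permutes sites so consecutive stimulations are ≥ d_min apart (randomized
greedy with restarts, seed-deterministic) to avoid photocurrent
accumulation; ensemble assignment grows k groups round-robin by greedy
farthest-point selection, maximizing within-ensemble minimum distance
(the sampler variant is this package's choice; no specific variant is
prescribed for ensemble assignment).

## Connectivity mapping

**Design.** P×V binary matrix; each repetition block is an independent
random partition of the (padded) voxel set into disjoint N-subsets, so rows
within a block are mutually orthogonal and P = M·V/N. "Orthogonal patterns"
is interpreted as within-block orthogonality — the only reading consistent
with P = MV/N, since rows from different repetitions necessarily overlap.
V not divisible by N is padded with flagged dummy voxels that are excluded
from the returned map.

**Inverse problem.** `argmin_{x≥0} ½‖Ax−y‖² + λ·R(x)` with R the
anisotropic total variation. The source formulation prints the regularizer
with a negative sign and without absolute values (which would telescope);
both are treated as typos — TV regularization is the named intent.
R is Σ|x_{j+1}−x_j| over raster order by default (1D, literal), with a
3D-neighbor option summing absolute forward differences along all axes.

**Solver.** FISTA: gradient step on the quadratic term with μ = 1/‖A‖₂²
(power iteration) unless overridden; prox of λ·TV via Condat's direct 1D
taut-string algorithm (exact, O(V)); projection onto x ≥ 0; Nesterov
momentum with function-value restart, so the objective is non-increasing
after any restart (a plain projected-gradient mode exists for literal
replication of simple gradient loops). The 3D TV prox is approximated by
alternating per-axis taut-string passes with λ/3 each — exact per axis,
approximate jointly; the 1D mode's prox is exact. Initialization is
uniform random in [0, 1] (seed-deterministic); stopping at maxiter (500) or
relative objective change below 1e-6. An objective increase on a *plain*
step (which is provably monotone for μ ≤ 1/‖A‖₂²) raises a step-size error;
nonnegative projection prevents NaN blow-up, so this is the practical
divergence signal. EPSC and IPSC maps are reconstructed separately as
nonnegative magnitudes with a polarity label.

**λ selection.** Default grid {0, ¼, ½, 1, 2} × sd̂ evaluated on a held-out
20% pattern split by validation residual, where sd̂ is a robust noise
estimate (1.4826·MAD of the lower half of y — multi-foci patterns that hit
no connected voxel measure pure noise, so with sparse maps the lower half
of y is noise-dominated).

**Metrics.** Relative ℓ₂ error ‖x̂−x‖/‖x‖; support F1 with "support" =
voxels ≥ 10% of the respective map's maximum. SNR is defined on power:
additive noise sd = rms(y_clean)/SNR.

**Trace analysis.** The mapping measurement is the peak magnitude of the
baseline-subtracted current in a post-stimulus window (default 50 ms — the
response window length is an experimental choice, exposed as a parameter).
Linear-summation analysis integrates |current| trapezoidally over the
window for the joint response and for the sum of baseline-subtracted
single-site responses. Calcium traces are z-scored per ROI against the
baseline window; for blanked-stimulus imaging the time origin is the start
of imaging (immediately after photostimulation), so the response window
starts at sample 0 and there is no pre-stimulus baseline — the z-score
baseline window must then be designated explicitly (e.g. a quiet span late
in the sweep); when no baseline window is set, traces are taken as already
baseline-normalized (zero mean, unit sd), which is how the synthetic
calcium generator emits them. The
(pattern × ROI) matrix averages each ROI's peak z over a pattern's
repetitions. ROI masks come from the maximum z-projection of a widefield
stack: quantile threshold, connected components, per-component dilation.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (spec, seed) — bit-identical reruns.

- **Phantoms**: truncated-Gaussian clusters (sd 15 µm, extent ≈ 30 µm,
  matching the cluster scale of real single-focus input maps) with uniform
  random centers and amplitudes 40–120 pA. A vanishing sd degenerates to a
  single-voxel source.
- **Noise**: additive Gaussian (default 5% of max response), per-pattern
  stimulation failures (default 5%, measurement collapses to baseline
  noise), multiplicative trial jitter (default sd 0.1). Chosen to make
  recovery nontrivial but achievable; all configurable.
- **Neuron fields**: dart-throwing Poisson-disc sampling with verified
  minimum separation (defaults in the 50–70 µm regime typical of sparse
  cortical labeling).
- **Calcium**: double-exponential transients (rise 50 ms, decay 1 s —
  slow-red-indicator-like fixture parameters, not indicator claims) at
  10 Hz framing, starting at the imaging onset; optional crosstalk gives
  neurons within a radius of a target an attenuated transient with
  Gaussian distance falloff (σ = radius/2) — a fixture convention, not a
  quantitative claim about off-target activation.
- **Widefield stacks**: Gaussian somata with defocus broadening away from
  each neuron's plane and Poisson photon noise.

What passing tests on these fixtures shows: the geometry, solver, and
analysis code are correct under the stated statistical assumptions
(linearity of summation, additive/failure noise, isolated clusters). What
they do not show: performance on real tissue — scattering, opsin kinetics,
dendritic stimulation, network adaptation and supra-linear integration are
outside the generators' scope.

## Numerical choices and limitations

- Sub-pixel aperture centers; no anti-aliasing on the DMD (binary mirrors).
- Bilinear mask sampling during shear; nearest-neighbor mode for oracles.
- FWHM interpolation linear; plateau handling as above.
- Angle count is configurable (default 10; up to the DMD frame budget,
  52 at 13 kHz and 4 ms, with diminishing optical benefit).
- Ring radius estimated as intensity-weighted mean radius; biased upward
  by ~r²/(4R²) for fat beams on tight rings (negligible at the tested
  geometries, < 0.5 µm).
- The solver's 3D TV mode requires V divisible by N (no dummy padding).
- `poisson_disc_order` is randomized-greedy with restarts, not an
  exhaustive search: feasible but adversarial instances may exhaust the
  restart budget.
- Study sizes used by the test suite and acceptance script (400-voxel
  maps, ≤ 52-frame renders on ≤ 120×120×241 grids, 100-trial calcium
  ensembles) were chosen as the smallest instances that exercise every
  claimed property cleanly.
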