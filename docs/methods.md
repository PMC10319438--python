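# Methods

This note records the models, parameter choices, numerical decisions, and
known limitations behind `ddrdyn`. Nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Simulator (ddrdyn.simkit)

The generator emulates fast HILO single-molecule acquisitions of
HaloTag-labeled nuclear proteins.

**State switching.** Each particle carries a continuous-time two-state
Markov chain (bound ↔ free) realized by exponential waiting times; the
initial state is drawn from the stationary distribution
F_bound = k_bind/(k_bind + k_unbind). Displacements over a frame interval
use the diffusion coefficient of the state occupying the majority of that
interval, and the recorded per-frame state is the chain state at the frame
time. This is the simplest realization consistent with a two-state mixture
analysis; sub-frame switching is therefore visible to the analysis only as
a mild mixing of jump populations.

**Geometry.** Lateral motion reflects at the edges of the simulated field
(default 170×140 px × 0.16 µm, the size of a typical camera crop). Axial
motion is 1D Brownian motion reflecting at a nuclear envelope of depth
4 µm (a typical adherent-cell nucleus), with the 0.7 µm detection slice
centered inside; a particle is visible in a frame iff its axial position
at that frame time lies within the slice. The envelope matters: without
it, free molecules drift axially away for good, the two states no longer
share the equilibrium in-slice occupancy dZ/depth, and any
occupancy-based mixture weight is wrong by construction. Axial starting
positions are uniform over the nucleus (`z_init="slice"` restricts them
to the slice, used when simulating the visible subpopulation of a
chromatin-locked species).

**Noise and loss.** Observed positions add i.i.d. Gaussian localization
error per axis (default σ = 35 nm — a typical value for this class of
experiment; the microscope's actual precision is a free parameter).
Photobleaching is exponential; the default half-life of 7.7 s is the
measured fluorescence half-life of a chromatin-locked control under
residence-imaging illumination. Full-power fast-tracking illumination
bleaches much faster; the diffusion validation studies use 50 ms (≈7-frame
mean track length, typical of such data). Movie rendering draws each
visible particle as a 2D Gaussian (pixel sum = photon budget) over a
constant background, with Poisson shot noise and optional Gaussian read
noise — the standard EMCCD approximation.

**Seeding.** One master seed spawns an independent stream per particle id,
so enlarging `n_particles` never reshuffles existing particles; equal
seeds give bit-identical output.

**What the generator does not emulate:** intranuclear structure
(chromatin-density heterogeneity, nucleoli exclusion), anomalous
diffusion, soft axial detection profiles (visibility is a hard slab),
camera gain calibration, and laser-damage chemistry. Passing tests show
the analysis chain is self-consistent and unbiased under this model, not
that real data meet its assumptions.

## Tracking (ddrdyn.tracking)

Detection thresholds candidate maxima (robust background median + k·MAD,
with k expressed as a log₁₀ per-pixel false-positive rate, default −5)
and refines each by least-squares 2D Gaussian fitting in a window of
±3 PSF sigmas. Linking is optimal bipartite assignment (Hungarian
algorithm) on squared displacement per frame, gated by
r_max(g) = √(4·D_max·(g+1)·Δt)·margin for a gap of g ≤ 2 missed frames;
margin defaults to 3, covering >99% of Brownian steps at D_max. Tracks
shorter than 3 localizations are discarded. Exact cost ties resolve by
the assignment solver's deterministic order after an intra-frame sort, so
linking is invariant to input order. Track duration counts first to last
frame inclusive, gaps included. The detector deliberately has no
deflation loops or multi-emitter fitting; two emitters within ~3 px merge
into one localization, which is why validation renders sparse fields with
separated starts.

## Diffusion fitting (ddrdyn.diffusion)

Jump histograms use lags 1..7 (8 time points), 0.01 µm bins, and only
gap-free spans. Two counting conventions are supported. The classic
per-trajectory cap (first 4 jumps per lag) limits oversampling of long
tracks, but because a fast molecule generates many short visibility
segments while a bound molecule generates one long track, per-segment
capping systematically reweights the states and biases F_bound — on
simulated ground truth at a 50 ms bleach half-life the bias reaches
−0.16. The package's estimator therefore defaults to counting **all**
gap-free jumps in its pipelines: then the expected jump count per state
at lag n is proportional to (frame occupancy) × (survival weight), which
is exactly what the model assumes, and recovery is unbiased to within a
few percent. The capped convention remains available for compatibility.

The mixture weight of state s at lag n is f_s·Z_s(n), renormalized per
lag. Z is the survival of a 1D Brownian particle started uniformly in the
detection slab. Two versions exist: the continuous absorbing-slab
eigenseries S(t) = (8/π²)Σ_odd k⁻² exp(−k²π²Dt/dZ²)
(`defocus_fraction`, truncated at 10⁻¹², validated against a
Brownian-bridge-corrected Monte-Carlo to <10⁻³), and a frame-**sampled**
variant (`slab_survival_sampled`, computed by numerical kernel
propagation) in which the particle must be inside the slab only at the
sampled frame times. Visibility on movies is scored at frame times, so
molecules that dip out and return between frames are never lost; the
sampled variant is therefore the correct weight for fitting and is the
default, while the continuous series is the cleaner mathematical object
and the one checked against the Monte-Carlo oracle. Whether the original
tools renormalize all state weights after correction or rescale only the
free component is ambiguous; this package renormalizes.

Fitting is bounded least squares (trust-region reflective) on the
difference between empirical and model densities stacked over all lags —
PDF fitting, zero-count bins retained — started from a deterministic
lattice over the bounds (3×3×3 for two states; log-spaced in D) with ties
broken by residual then lower D_free. Bounds default to
D_free ∈ [0.5, 25], D_bound ∈ [0.0001, 0.5] µm²/s; the three-state
variant adds D_free2 ∈ [0.05, 5] and parametrizes the fraction simplex as
(p, (1−p)q). σ is a fixed input, not fitted: the data rarely constrain it
jointly with D_bound at desk scale.

Residual biases of the whole chain, measured on synthetic ground truth at
~6×10⁴ lag-1 jumps: |ΔF_bound| ≤ 0.03 and D_free within −7% across
F_bound ∈ {0.2, 0.5, 0.66} × D_free ∈ {1, 2, 4} µm²/s. The D_free
underestimate comes from sub-frame state switching and the uniform-start
approximation in the survival weights, and is inherent to finite-lag
mixture fitting of switching particles.

## Residence analysis (ddrdyn.residence)

Block averaging is non-overlapping (a sliding window would not change the
effective frame rate). Bound tracking constrains D_max to 0.5 µm²/s by
default — the alternative 0.05 µm²/s convention is exposed as a parameter
— with zero gap allowance, the stricter choice that avoids stitching
separate binding events. Survival fitting is unweighted least squares on
S(τ) at the observed unique durations (fitting survival probability, not
binned frequencies), with τ measured from the minimum trackable duration
and components ordered t_fast ≤ t_slow. Tracks lasting the whole movie
are censored; `fit_biexponential(tau_max=...)` excludes them from the fit
(forcing S→0 at the window end biases the slow component down) and
`fraction_exceeding` reports them separately.

Two stabilizers address the well-known ill-conditioning of two-component
decompositions on nearly single-exponential survival data. First, among
multi-start optima whose residuals agree within 1%, the fit reports the
smallest slow half-life — the data cannot distinguish these solutions,
and the conservative reading never asserts slower binding than the curve
resolves. Second, a solution that is still degenerate (a component with
<2% weight, or a half-life beyond twice the observed duration span —
unmeasurable within the record) collapses to the single-exponential fit
with both half-lives equal. Genuine two-component data (distinct
half-lives with non-trivial weights) are unaffected by either rule.
Bleach estimation fits a single exponential to background-subtracted
integrated masked intensity and flags non-decaying signals (<1% decay
over the record).

The validation study renders 96 movies of 15 permanently bound, immobile
molecules each (128×128 px, in-slice starts separated by ≥8 px — emitters
inside one PSF merge into a single spot whose duration is the maximum of
two bleach times, a detector artifact rather than a residence signal —
7.7 s bleach, ~1,400 durations) and recovers the bleach half-life as the
slow component within a few percent. With axial mobility switched on the
hard slice edge fragments tracks and the recovered half-life drops — the
focal-plane-drift underestimation that residence measurements of this
kind are known to carry.

## Recruitment (ddrdyn.recruitment)

Registration is translation-only phase cross-correlation to the first
frame (sub-pixel, linear interpolation). Baseline subtraction uses all
pre-irradiation frames by default; irradiation is placed at the last
baseline frame. Per-cell curves normalize to their own brightest frame,
the cell average renormalizes its brightest mean frame to 1, and the fit
pins Y0 = 0 and plateau = 1. Peak normalization on noisy data scales the
curve by the expected maximum of the noise, which biases t₁/₂ upward by
roughly the relative ROI noise times the extreme-value factor; with the
~1% ROI noise typical of averaged ROIs and acquisitions running to ≥6
half-lives (the validation conditions), the end-to-end bias stays within
a few percent. Cells at different frame rates are fit separately; curves
of unequal length truncate to the shortest.

## Abundance (ddrdyn.abundance)

Standard curves are ordinary least squares with a free intercept (gel
backgrounds are nonzero). The TEV factor is the loading-normalized
cleaved/uncleaved ratio applied multiplicatively to fusion signal; the
western factor multiplies by the untagged/tagged expression ratio. Error
propagation adds relative variances in quadrature for products and
quotients. The cell-number curve can either supply the cell count
(loading normalization, default) or be bypassed with a direct count.
Signals at or below the blank raise a non-quantifiable flag rather than
returning a number.

## Pipelines and I/O (ddrdyn.workbench)

Frames are 0-based, distances in µm, times in seconds, everywhere.
Trajectories interchange as `track_id,frame,x_um,y_um,intensity` CSV with
strictly-increasing frames enforced on read (errors name the line).
Movies are multi-page TIFF with a `key=value` sidecar carrying
`frame_interval_s` and `pixel_size_um`. Configs are flat `key=value`
files with dotted stage prefixes; unknown keys are rejected. Pipelines
are deterministic given the seed and log every parameter used.

## Validation problem sizes

Chosen to give each estimate comfortably more data than its tolerance
needs: 42,000 particles × 100 frames per grid point for diffusion
recovery (≥5×10⁴ lag-1 jumps each), 10⁶ walkers for the slab oracle, 96
movies for residence (~1,400 durations), 10 cells per recruitment
condition, 10⁴ durations for biexponential recovery, and 6 sparse movies
(~3,600 links) for the tracking round trip.

## Known limitations

* The mixture model ignores within-lag state switching; it costs a few
  percent on D_free and grows with the switching rates.
* The defocus weights assume a uniform in-slice start for every jump;
  selection effects from finite segments are second-order but nonzero.
* Hard-edge axial visibility exaggerates flicker of molecules near the
  slice boundary relative to a real soft detection profile.
* The detector merges emitters closer than ~3 px; crossing trajectories
  swap or break, so link-recovery guarantees hold only for sparse fields.
* Residence times are bleach- and defocus-limited upper-bound
  measurements by construction.
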