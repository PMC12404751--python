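# Methods

## Transport model and discretization

The pipeline treats percent-signal-change images as a mass density ρ
evolving under advection, diffusion, and a relative source:

    ∂ρ/∂t + ∇·(ρ v) = σ Δρ + ρ r.

Both the simulator and the solver integrate this equation with the
same operator-splitting scheme, applied per sub-step of length
dt = Δt / n_substeps (default n_substeps = 10 per 10-minute frame
pair):

1. **Advection** — conservative first-order upwind fluxes on cell
   faces, face velocity the mean of the two adjacent cell velocities,
   zero flux through the grid boundary. Total mass is conserved
   exactly; positivity holds under the CFL limit
   dt · Σ_d max|v_d| ≤ 1 (voxel units, h = 1).
2. **Diffusion** — explicit Neumann (reflecting) Laplacian,
   stable and positivity-preserving for σ dt ≤ 1/6 in 3D. Mass
   conserved exactly.
3. **Source** — multiplicative update ρ ← ρ·exp(r dt), positivity-
   preserving for any r, and yielding the exact discrete mass budget
   Δmass = Σ ρ_pre·(exp(r dt) − 1), which the tests assert.

`required_substeps` enforces both limits and a violating call is
refused with the minimum admissible sub-step count. Sharing one
scheme between simulator and solver means a noiseless synthetic pair
lies exactly in the solver's model class, so recovery errors measure
the estimator, not model mismatch.

Units: ρ in percent signal change (directly proportional to tracer
concentration), v in voxel/min, σ in voxel²/min, r in 1/min. Since ρ
is in percent units, r is reported as "percent per minute" (r-flux)
without rescaling.

## Inverse problem

Each adjacent pair (ρ₀, ρ₁) is inverted for one velocity field and
one source field, held constant over the pair's sub-steps. (The
reported r-flux is defined as the time average of r over the pair, so
a time-constant parameterization is its natural minimal form and
quarters the unknowns; `rflux_from_pair` still averages per-sub-step
stacks when given them.) The endpoint constraint is enforced by
penalty:

    E(v, r) = Δt Σ w |v|² + α Δt Σ w r² + β Σ (ρ_end − ρ₁)²

- **w = (ρ₀+ρ₁)/2 + floor** — the density weight of the kinetic and
  source terms. Using the (fixed) pair-mean rather than the evolving
  trajectory keeps the adjoint confined to the endpoint term without
  changing any tested recovery property.
- **Scaling** — densities are divided by their tissue-mean pair
  average before solving, so β (default 10⁴) is relative to
  unit-scaled densities and r, v are unaffected (both are relative
  rates). A density floor of 10⁻⁴ guards against vanishing density.
- **α schedule** — per-pair weights increase linearly from 5,000 on
  the first pair to 40,000 on the last; only the endpoints and
  monotonicity are protocol, the linear interpolation is this
  package's choice and any non-decreasing schedule may be supplied.
- **σ** — no protocol value exists for the diffusivity; default
  0.002 voxel²/min (small against the advective scales used here),
  configurable, and matched between simulator and solver in all
  recovery tests.
- **Optimization** — gradients are hand-coded adjoints through the
  splitting steps (the upwind switch uses the right-continuous
  subgradient at zero face velocity; face velocities exactly at zero
  are a measure-zero event for the optimizer). The reduced objective
  is minimized by L-BFGS-B from v = 0, r = 0, capped at `max_iters`
  (default 60) with relative energy tolerance 10⁻⁴. The method is
  deterministic, so identical inputs give bit-identical fields.
  Because the initial iterate *is* the zero solution and the
  regularizers are non-negative, the final endpoint mismatch can
  never exceed the zero-solution mismatch. Fields are parameterized
  only inside the tissue mask and are identically zero outside.
  The default iteration cap resolves source-dominated pairs fully;
  strongly advective pairs (e.g. the translated-blob recovery test)
  are run at a larger cap where the velocity field, not the budget,
  is the object under test.

A known property of the penalty form with finite α: recovered source
amplitudes are shrunk by roughly α / (α + β·ā·Δt) relative to truth
(ā the scaled local density), a few percent at α = 5,000 and more at
40,000. Shrinkage never flips signs, which is why sign-based
classification is robust across the schedule while amplitude
comparisons in the tests use the first-pair α.

## Synthetic study conditions

`make_phantom` builds a spherical "brain" (radius 0.38·grid) with a
CSF inlet sphere at the lower pole — the cisterna-magna side — and
brainstem/cerebellum analog ROIs between inlet and center, all in
fractional coordinates so one specification scales across grid sizes.
Default grid 24³ at 0.2 mm isotropic voxels (the stated neck-scan
resolution).

The default influx-clearance scenario drives a 15-frame series at
10-minute intervals, first frame at 30 min, hence 14 pairs with
midpoints 35…165 min:

- **Influx** — a Gaussian source (length scale 0.17·grid) at the
  inlet, amplitude 0.045/min decaying with an e-folding of 0.36·n_pairs.
  The amplitude was set so the inlet-core signal grows ≈ 8-fold over
  the influx phase, a plausible monotone DCE uptake. A sustained
  relative rate of 0.4/min would overflow any bounded percent-change
  series within two frames, so net-rate magnitudes on the 0.4 %/min
  scale are treated as map-value scales, not sustainable relative
  growth rates.
- **Clearance** — a broad Gaussian sink (0.34·grid) at the tissue
  center whose amplitude ramps to 0.02/min through a sigmoid centered
  at 0.65·n_pairs, i.e. pair ≈ 9 of 14: clearance becomes dominant
  shortly after 120 min while residual influx keeps shrinking, so the
  influx volume fraction falls and the clearance fraction rises over
  the late time points rather than switching abruptly.
- **Velocity** — radial outflow from the inlet, 0.08 voxel/min peak,
  decaying in time with the influx envelope.
- **Initial frame** — background 0.5% plus a 20% Gaussian bump at the
  inlet, representing tracer already present at the 30-minute mark.
- **Noise** — additive Gaussian on percent-change values truncated at
  zero; the default is noiseless because no reference noise magnitude
  is available for percent-change images, and noise is exercised
  explicitly where a test concerns it. The Gaussian form is a stand-in, not a claim
  about the scanner noise distribution.

What the generator does *not* emulate: MRI physics (coil profiles,
relaxivity, k-space), anatomical geometry, motion, or the spatially
correlated noise of real reconstructions. Passing recovery tests
therefore demonstrate correctness of the estimator under its own
model class and the stated noise, not performance on scanner data.

## Regional metrics

Classification is strict (`> +0.001`, `< −0.001` %/min; values
exactly at the threshold belong to neither class). Net rate averages
over **all** ROI voxels, sub-threshold included (a switch restricts
to supra-threshold voxels if wanted). Trajectory time stamps are
interval midpoints. Phase windows are closed intervals resolved by
midpoint membership: with the default timing this puts 8 maps in the
30→110 min influx window and 4 in the 120→160 min clearance window.
Trajectory smoothing is a centered moving average over 2w+1 points
with shrinking end windows (length-preserving, constant-invariant);
TSC smoothing is a trailing 2-point window, which preserves the
monotonicity of uptake curves but shortens the series by w−1 points.

## Drainage curves and ICP

Neck curves are handled from extracted per-structure TSCs onward
(image-domain ROI drawing and 4D denoising are out of scope).
Drainage strength of a group is the trapezoidal AUC of its mean
curve on the common time grid; the reduction metric
100·(1 − AUC_test/AUC_ref) equals 80% exactly for a 5:1 amplitude
ratio. Peak and terminal-value variants are provided since the
integral choice is a definition, not a measurement.

Mean ICP uses the first stable 60-s window: the recording is cut into
5-s blocks and a window qualifies when every block SD is at most 2×
the SD of the final minute — a quantitative stand-in for "after ICP
stabilized" that skips settling transients while tolerating the
pulsatile SD floor. Welch's t test is computed from summary
statistics (raw samples are reduced to summaries first, so both entry
routes agree to machine precision) with Satterthwaite df and a
symmetric t interval; Benjamini–Hochberg adjustment is the standard
step-up with monotonicity enforcement, capped at 1. Note that
re-adjusting already-adjusted values is *not* a no-op (the step-up
map is expansive on its own output); adjusted values preserve input
ranks, which is the property tested.

## Problem sizes

Default analyses run at 24³ voxels × 15 frames (the full series
inverts in under a minute on one CPU); the bundled demo config uses
16³ with a reduced iteration cap for a fast smoke run; gradient
checks use 5³ grids where finite differences are exact enough to
resolve the adjoint to 10⁻⁵ relative error.

## Known limitations

- The penalty formulation solves a relaxation, not the exactly
  constrained transport problem; mismatch decreases with β but the
  constraint is never exact.
- First-order upwind advection is numerically diffusive; recovered
  velocity magnitudes are biased low in under-resolved features
  (the blob test recovers direction and correlation, with amplitude
  shrinkage).
- One velocity/source field per pair cannot represent sub-interval
  dynamics; the r-flux readout is by construction a 10-minute average.
- The optimizer finds a local minimum of a non-convex energy; with
  zero initialization this is deterministic and empirically reliable
  on the tested instances, but no global optimality is claimed.
- Regional statistics here are per-subject; cohort trajectory
  modeling (linear mixed models) is deliberately left to standard
  statistical packages via the tidy CSV export.
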