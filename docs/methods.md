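# Methods

## Signal model

The ball & stick model decomposes the voxel signal into an isotropic
compartment and L axially symmetric, perfectly anisotropic compartments:

    S_i = S0 [ (1 − Σ_j f_j) e^{−b_i d} + Σ_j f_j e^{−b_i d (r_i·x_j)²} ],
    x_j = (sin θ_j cos φ_j, sin θ_j sin φ_j, cos θ_j).

The signal depends on x_j only through (r·x)², so orientations are axial:
a stick and its antipode are indistinguishable. Angles are therefore kept
unconstrained throughout (no wrapping into (0, π) × (−π, π]); a canonical
hemisphere is applied only when reporting dyads. b = 0 measurements stay
inside the signal vector — the model reduces to S0 there exactly — so the
likelihood and the least-squares stage see one homogeneous vector. The
parameter count is R = 3L + 2.

Assumptions: single shell (one non-zero b-value is typical but not
required), no noise-floor term in the forward model, no tensor
compartments, diffusivity shared by all compartments.

## Stage 1 — Levenberg–Marquardt

A damped Gauss–Newton iteration minimises the sum of squared residuals,
with an analytic Jacobian (cross-checked against central finite
differences in the tests). Constraints are handled by an internal
reparameterisation — S0 = s², d = u², f_j = sin² w_j — and by projecting
each candidate onto the simplex Σ f_j ≤ 1 *before* evaluating it; a step
is accepted only if the projected candidate strictly lowers the sum of
squares, which makes the accepted trace non-increasing by construction.

Initialisation: S0 is the mean b=0 signal; a log-linear diffusion-tensor
fit supplies d (mean eigenvalue), the first stick (principal eigenvector)
and f_1 (fractional anisotropy clipped to [0.01, 0.95]); additional
sticks start at the remaining eigenvectors with f_j = f_1/(j+1). A
singular tensor system falls back to a small isotropic start (f_j = 0.05,
coordinate-axis orientations, d from the median apparent diffusivity).

Defaults: damping λ = 10⁻³, ×10 on rejection, ×0.1 on acceptance;
stop on relative improvement < 10⁻⁹ (ftol), a machine-precision fit
(SSR ≤ 10⁻²⁰ · Σ data²), damping exhaustion (λ > 10¹²), or 200
iterations. The stage is deterministic: identical inputs give bitwise
identical outputs.

## Stage 2 — random-walk Metropolis

The Gaussian noise variance is marginalised analytically under a
noninformative (Jeffreys-type) prior, giving

    log L = −(K/2) · log SSR(params),

with SSR floored at 10⁻¹² so exact fits stay finite. Priors: flat on
S0 ≥ 0 and d ≥ 0, flat on the volume-fraction simplex, and
uniform-on-the-sphere for each orientation, implemented as a |sin θ|
density. The absolute value (rather than sin θ with support (0, π))
keeps the axial density correct when the unconstrained random walk
carries θ past a pole; gating the support instead would trap chains near
polar orientations.

Parameters are updated one at a time in the fixed order S0, d, then
(f, θ, φ) per stick — the order that indexes the random streams. Each
update consumes exactly one Normal draw (proposal) and one Uniform draw
(acceptance), whether or not the proposal is rejected early by the prior.
Proposal standard deviations start at scale-aware defaults (5% of S0,
10% of d, 0.05 for f, 0.1 rad for angles) and adapt during burn-in only:
every 40 iterations each sd is multiplied by (acceptance fraction / 0.5)
clipped to [0.5, 2]; adaptation freezes after burn-in so the retained
samples target the exact posterior. Chain defaults (burn-in 3000,
1250 jumps, thinning 25 → 50 retained samples per parameter) follow the
bedpostX-style convention for this model family.

All randomness is pre-generated: `generate_stream(seed, opts, R)` fills
(burn-in + jumps) × R Normal and Uniform buffers from numpy's PCG64.
A chain is thereby a pure function of (data, scheme, init, options,
stream) — reruns are bitwise identical, and the two execution engines
can be compared draw for draw.

## Batched execution engine

The volume driver mirrors a GPU-style decomposition in numpy terms:

* LM is data-parallel over voxels (independent scalar fits, grouped into
  batches);
* the batched MCMC kernel advances up to `batch_size` voxel chains in
  lock-step, vectorising the proposal, the K signal evaluations, the
  prior support test and the accept/reject bookkeeping across the batch,
  while the scalar decision logic per voxel is unchanged;
* slices (third spatial axis) are partitioned across workers greedily by
  masked-voxel count; workers share nothing mid-run.

Numerical equivalence with the serial reference is engineered, not
hoped for: both engines order every floating-point operation identically
(per-stick accumulation in stick order, explicit 3-term dot products) and
funnel the residual reduction through one function (`sum_sq`, a
contiguous `np.dot`) so the reduction order is fixed. On this numpy
build, elementwise ufuncs give bitwise identical results for scalar,
contiguous and strided operands, so the engines agree exactly; the
equivalence test still asserts at 1e-9 relative, a tolerance that would
also absorb platform-level ulp differences in vectorised math kernels.
`batch_size` (default 64, a good lock-step width for this workload) and
`workers` are pure performance knobs with no effect on results: per-voxel
stream seeds are `base_seed + linear voxel index`, independent of
partitioning.

## Synthetic data

`make_scheme` builds a single-shell design — K directions from the
deterministic spherical Fibonacci lattice folded onto the upper
hemisphere (adequate uniformity for axial sampling; minimum pairwise
separation 2.28° at K = 64), plus n_b0 unweighted measurements. Defaults
K = 64, b = 2500 s/mm², one b=0, emulating a high-b research
acquisition. SNR is defined at b = 0 as S0 over the noise standard
deviation; Gaussian noise is additive, Rician noise takes the magnitude
of the complex-perturbed signal. The canonical phantom stacks three
regions — isotropic (f = 0), single fibre (f = 0.7, generic orientation
θ = π/3, φ = π/4) and a 90° crossing (f1 = f2 = 0.35 along x and y) — at
S0 = 100, d = 10⁻³ mm²/s, SNR 30 by default: a white-matter-like regime
in which both stages are exercised away from degenerate corners.

The generator emulates thermal noise only. Real acquisitions add eddy
currents, motion, susceptibility distortion, spatially varying noise and
imperfect gradient tables; passing tests here demonstrate correctness of
the estimator and of the parallel decomposition, not robustness to
acquisition artefacts.

## Validation design

Two complementary engine comparisons are used. The shared-stream check
feeds both engines identical pre-generated random numbers and requires
the retained samples to match (≤ 1e-9 relative; bitwise in practice).
The repeated-execution check runs each engine many times with disjoint
seed blocks on representative voxels and compares the per-parameter
distributions of posterior means with two-sample KS tests; a negative
control (volume-fraction prior support widened to [−1, 1], which shifts
the posterior of an isotropic voxel off the f ≥ 0 boundary) must be
detected. Orientation parameters enter the KS comparison as the dyad's
polar/azimuthal angles on the canonical hemisphere.

Recovery thresholds are frozen from a 10× longer reference chain
(12 500 jumps, same thinning) under identical phantom conditions:
single-fibre median dyad error 0.646° and median |f̂ − f| 0.0155;
crossing median per-voxel worst dyad error 1.90°. Checks use 2.5× these
medians (single fibre ≤ 1.614° and ≤ 0.0387; crossing: ≥ 80% of voxels
below 4.755°). The margin covers the default chain's extra Monte Carlo
error and the sampling variability of a 50-voxel median across noise
realisations, which repeated reference-condition runs showed to dominate
the chain-length effect. `scripts/make_reference_thresholds.py`
regenerates these numbers.

Problem sizes (50 voxels per recovery phantom, 50 repeats and 3 voxels
for the KS comparison, 20 voxels for the shared-stream check, 50 000
iterations for the tractable-target check) were chosen so the whole
validation runs in minutes on one core while keeping Monte Carlo error
well below the thresholds being asserted.

## Numerical choices and edge cases

* SSR floor 10⁻¹² in the marginalised likelihood; without it a perfect
  fit has infinite posterior density.
* b-values below 50 s/mm² are treated as unweighted on input (scanner
  b=0 volumes are rarely exactly zero).
* LM initialisation on boundary values is nudged strictly inside the
  prior support (ε = 10⁻⁶) before sampling, since the flat priors give
  the boundary zero density under the proposal cache.
* Tie-break in `dyadic_mean`: the principal eigenvector's sign is chosen
  with z ≥ 0 (axial data carry no sign).
* Degenerate voxels: all-b0 data raise an initialisation error; a
  singular tensor fit falls back to the isotropic start; empty masks
  return zero maps with a warning.

## Known limitations

Single diffusivity shared across compartments and no Rician likelihood
(Rician *simulation* is provided; at SNR ≳ 20 the Gaussian approximation
biases f and d only mildly). No automatic relevance determination on
higher sticks: with L larger than the true fibre count the surplus stick
absorbs a small fraction (visible as f1 ≈ 0.65 when fitting L = 2 to an
f = 0.7 single-fibre voxel). No convergence diagnostics beyond
acceptance fractions. The CLI loads the whole 4D volume into memory.
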