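# ballstick

Voxelwise Bayesian estimation of white-matter fibre orientations from
diffusion-weighted MRI with the ball & stick model, for researchers who
need crossing-fibre posterior distributions (as consumed by probabilistic
tractography) together with an execution engine that scales over voxels
without changing the answer.

## The model and the method

A diffusion-weighted measurement along unit gradient direction
**r**<sub>i</sub> with b-value b<sub>i</sub> is modelled as one isotropic
compartment (the *ball*) plus L perfectly anisotropic compartments (the
*sticks*):

    S_i = S0 [ (1 − Σ_j f_j) e^{−b_i d} + Σ_j f_j e^{−b_i d (r_i·x_j)²} ]

where S0 is the unweighted baseline signal, d the diffusivity (mm²/s),
f_j ∈ [0,1] the volume fraction of stick j (Σ f_j ≤ 1) and
x_j(θ_j, φ_j) its orientation. Each voxel is fit independently in two
stages:

1. **Levenberg–Marquardt** — a deterministic damped least-squares fit
   (seeded by a log-linear diffusion-tensor fit) that minimises the sum of
   squared residuals and provides the MCMC starting point;
2. **random-walk Metropolis MCMC** — single-parameter Normal proposals in
   fixed order (S0, d, then per stick f, θ, φ), with the Gaussian noise
   variance marginalised analytically, so the log posterior is
   −(K/2)·log SSR plus noninformative priors (flat on S0 ≥ 0, d ≥ 0 and
   the f-simplex; uniform-on-sphere orientations). The default chain
   discards 3000 burn-in iterations, then retains every 25th of 1250
   jumps — 50 posterior samples per parameter.

Posterior orientation samples are axial quantities and are summarised by
the **dyad** (principal eigenvector of the mean outer-product tensor) and
its **dispersion** eigenvalue (1/3 = isotropic, 1 = concentrated).

All Normal and Uniform draws a chain will consume are pre-generated as a
per-voxel `RandomStream`. A **batched engine** advances many voxel chains
in lock-step with vectorised signal evaluation; because it consumes the
same streams and performs the same floating-point operations in the same
order as the serial reference, the two engines agree *bitwise* — the
parallel decomposition is a re-organisation of the arithmetic, not an
approximation. Slices are additionally distributed over independent
workers, and results are invariant to batch size and worker count.

## Worked example

`examples/02_fit_single_voxel.py` simulates one voxel (f = 0.7, SNR 30,
64 directions at b = 2500 s/mm²) and runs the full two-stage fit:

```
LM stage: 5 iterations, final sum-of-squares 476.6, converged=True
retained samples per parameter: 50
posterior mean S0 = 97.79  (truth 100)
posterior mean d  = 1.03e-03  (truth 1.0e-03 mm^2/s)
posterior mean f1 = 0.719  (truth 0.700)
dyad angular error = 1.30 deg
orientation dispersion eigenvalue = 0.9998 (1 = perfectly concentrated)
```

The posterior means land on the ground truth to within the posterior
width at this SNR; the dyad (axial mean orientation) is 1.3° from the
true fibre axis, and a dispersion eigenvalue near 1 says the orientation
posterior is tightly concentrated. The other scripts in `examples/`
demonstrate the forward model, whole-volume fitting on the canonical
three-region phantom, the bitwise engine-equivalence check, and the
repeated-execution KS comparison.

## Command line

```sh
ballstick phantom --n-per-region 16 --snr 30 --out phantom/
ballstick fit --data phantom/data.nii.gz --mask phantom/mask.nii.gz \
    --bvecs phantom/bvecs --bvals phantom/bvals --nfibres 2 \
    --seed 1 --workers 2 --out maps/
ballstick validate --repeats 50 --seed 1
```

`fit` writes FSL-style 32-bit NIfTI maps (`mean_dsamples`,
`mean_S0samples`, `mean_f{j}samples`, `dyads{j}`, `dispersion{j}`).
bvecs are taken in the image frame exactly as given — no gradient-table
reorientation is applied.

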