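"""Synthetic acquisition schemes and ground-truthed phantoms.

Emulates a single-shell whole-brain-style acquisition: K evenly spaced
gradient directions at one b-value plus unweighted (b=0) volumes, with
voxel signals drawn from the ball & stick forward model under Gaussian or
Rician noise at a stated SNR (defined at b=0 as S0 divided by the noise
standard deviation).  Everything is deterministic given a seed, so test
fixtures are generated rather than stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AcquisitionScheme, BallStickParams, predict_signal

__all__ = [
    "PhantomSpec",
    "Region",
    "make_scheme",
    "simulate_voxel",
    "make_phantom",
    "canonical_phantom_spec",
]

#: default acquisition: 64 directions at b = 2500 s/mm^2 plus one b=0
DEFAULT_K = 64
DEFAULT_BVAL = 2500.0

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def make_scheme(K: int = DEFAULT_K, bval: float = DEFAULT_BVAL, n_b0: int = 1) -> AcquisitionScheme:
    """Evenly spaced single-shell scheme from a spherical Fibonacci lattice.

    The K diffusion-weighted directions are the deterministic Fibonacci
    lattice on the sphere, folded onto the upper hemisphere (directions
    are axial, so a point and its antipode sample the same axis), followed
    by ``n_b0`` unweighted measurements.
    """
    if K < 6:
        raise ValueError("need at least 6 gradient directions (K >= 6)")
    if n_b0 < 1:
        raise ValueError("need at least one b=0 measurement")
    i = np.arange(K)
    z = 1.0 - (2.0 * i + 1.0) / K
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    az = GOLDEN_ANGLE * i
    dirs = np.column_stack([r * np.cos(az), r * np.sin(az), z])
    dirs[dirs[:, 2] < 0] *= -1.0  # hemisphere fold (axial sampling)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    bvals = np.concatenate([np.full(K, float(bval)), np.zeros(n_b0)])
    bvecs = np.vstack([dirs, np.zeros((n_b0, 3))])
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def simulate_voxel(
    params: BallStickParams,
    scheme: AcquisitionScheme,
    snr: float = np.inf,
    noise_model: str = "gaussian",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One voxel's measured signal under the stated noise model.

    Gaussian noise adds N(0, (S0/snr)^2) per measurement; Rician noise
    takes the magnitude of the signal perturbed by two independent such
    draws (real and imaginary channels).  ``snr=inf`` returns the exact
    forward prediction.
    """
    clean = predict_signal(params, scheme)
    if np.isinf(snr):
        return clean
    if snr <= 0:
        raise ValueError("snr must be positive (or inf for noiseless)")
    if rng is None:
        rng = np.random.default_rng(seed)
    sd = params.S0 / snr
    if noise_model == "gaussian":
        return clean + rng.normal(0.0, sd, clean.shape)
    if noise_model == "rician":
        n1 = rng.normal(0.0, sd, clean.shape)
        n2 = rng.normal(0.0, sd, clean.shape)
        return np.sqrt((clean + n1) ** 2 + n2**2)
    raise ValueError(f"unknown noise model {noise_model!r}")


@dataclass(frozen=True)
class Region:
    """A labelled block of voxels sharing one ground-truth parameter set."""

    name: str
    slices: tuple[slice, slice, slice]
    params: BallStickParams


@dataclass
class PhantomSpec:
    """Recipe for a ground-truthed phantom volume."""

    shape: tuple[int, int, int]
    regions: list[Region]
    snr: float = 30.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        cover = np.zeros(self.shape, dtype=int)
        for reg in self.regions:
            cover[reg.slices] += 1
        if np.any(cover > 1):
            raise ValueError("phantom regions overlap")


def canonical_phantom_spec(
    n_per_region: int = 16,
    snr: float = 30.0,
    noise_model: str = "gaussian",
    seed: int = 0,
    S0: float = 100.0,
    d: float = 1e-3,
) -> PhantomSpec:
    """Three-region test phantom: isotropic, single fibre, 90-degree crossing.

    Regions are stacked along the first axis, each a block of
    ``n_per_region`` voxels: pure ball (f = 0), one stick at f = 0.7
    (generic orientation, theta = pi/3, phi = pi/4), and two orthogonal
    in-plane sticks at f1 = f2 = 0.35 (x and y axes).
    """
    nz = max(2, int(np.ceil(n_per_region / 4)))
    ny = 2
    nx = int(np.ceil(n_per_region / (ny * nz)))
    shape = (3 * nx, ny, nz)
    regions = [
        Region(
            "isotropic",
            (slice(0, nx), slice(0, ny), slice(0, nz)),
            BallStickParams(S0=S0, d=d, f=[0.0], theta=[np.pi / 2], phi=[0.0]),
        ),
        Region(
            "single_fibre",
            (slice(nx, 2 * nx), slice(0, ny), slice(0, nz)),
            BallStickParams(S0=S0, d=d, f=[0.7], theta=[np.pi / 3], phi=[np.pi / 4]),
        ),
        Region(
            "crossing",
            (slice(2 * nx, 3 * nx), slice(0, ny), slice(0, nz)),
            BallStickParams(
                S0=S0,
                d=d,
                f=[0.35, 0.35],
                theta=[np.pi / 2, np.pi / 2],
                phi=[0.0, np.pi / 2],
            ),
        ),
    ]
    return PhantomSpec(
        shape=shape, regions=regions, snr=snr, noise_model=noise_model, seed=seed
    )


def make_phantom(
    spec: PhantomSpec, scheme: AcquisitionScheme
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Materialise a phantom: (data4d, mask, ground-truth maps).

    The mask covers exactly the union of the regions.  Ground-truth maps
    include per-voxel S0, d, per-stick f and stick direction, plus an
    integer region-label map (0 outside the mask, regions numbered from 1)
    and the region names.
    """
    K = scheme.n_measurements
    data = np.zeros(spec.shape + (K,))
    mask = np.zeros(spec.shape, dtype=bool)
    Lmax = max(reg.params.n_sticks for reg in spec.regions)
    truth = {
        "S0": np.zeros(spec.shape),
        "d": np.zeros(spec.shape),
        "f": np.zeros((Lmax,) + spec.shape),
        "dirs": np.zeros((Lmax,) + spec.shape + (3,)),
        "label": np.zeros(spec.shape, dtype=int),
    }
    rng = np.random.default_rng(spec.seed)
    snr = np.inf if np.isinf(spec.snr) else spec.snr
    for li, reg in enumerate(spec.regions, start=1):
        mask[reg.slices] = True
        truth["label"][reg.slices] = li
        truth["S0"][reg.slices] = reg.params.S0
        truth["d"][reg.slices] = reg.params.d
        for j in range(reg.params.n_sticks):
            truth["f"][(j,) + reg.slices] = reg.params.f[j]
            from .model import stick_direction

            truth["dirs"][(j,) + reg.slices] = stick_direction(
                reg.params.theta[j], reg.params.phi[j]
            )
        ii, jj, kk = np.nonzero(truth["label"] == li)
        for i, j, k in zip(ii, jj, kk):  # fixed voxel order for determinism
            data[i, j, k] = simulate_voxel(
                reg.params, scheme, snr=snr, noise_model=spec.noise_model, rng=rng
            )
    truth["region_names"] = np.array([reg.name for reg in spec.regions])
    return data, mask, truth
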