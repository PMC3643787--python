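"""Posterior summaries and the repeated-execution engine comparison.

Orientations are axial quantities (a stick and its antipode are the same
fibre), so they are averaged through the mean dyadic tensor
``(1/n) sum_i x_i x_i^T``: the *dyad* is its principal eigenvector and the
*dispersion* its largest eigenvalue, which ranges from 1/3 (isotropic
orientation samples) to 1 (perfectly concentrated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import ks_2samp

from .mcmc import PosteriorSamples
from .model import stick_direction

__all__ = [
    "VolumeResult",
    "posterior_means",
    "dyadic_mean",
    "angular_error",
    "paired_angular_errors",
    "repeat_validation",
]


@dataclass
class VolumeResult:
    """Per-voxel posterior summary maps over a masked 3D grid.

    All maps are zero outside the mask; dyads are unit vectors on masked
    voxels and dispersions lie in [1/3, 1].
    """

    mask: np.ndarray  # (X, Y, Z) bool
    n_sticks: int
    mean_S0: np.ndarray  # (X, Y, Z)
    mean_d: np.ndarray  # (X, Y, Z)
    mean_f: np.ndarray  # (L, X, Y, Z)
    dyads: np.ndarray  # (L, X, Y, Z, 3)
    dispersion: np.ndarray  # (L, X, Y, Z)
    samples: dict[str, np.ndarray] = field(default_factory=dict)
    # merged retained samples, name -> (X, Y, Z, n_retained)

    @classmethod
    def empty(cls, shape: tuple[int, int, int], mask: np.ndarray, L: int) -> "VolumeResult":
        return cls(
            mask=mask.astype(bool),
            n_sticks=L,
            mean_S0=np.zeros(shape),
            mean_d=np.zeros(shape),
            mean_f=np.zeros((L,) + shape),
            dyads=np.zeros((L,) + shape + (3,)),
            dispersion=np.zeros((L,) + shape),
        )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def posterior_means(samples: PosteriorSamples) -> dict[str, float | np.ndarray]:
    """Posterior mean of every model parameter for one voxel.

    Scalar parameters (S0, d, f_j) are arithmetic means of the retained
    samples; each stick orientation is summarised by its dyadic mean and
    dispersion rather than by naive angle-averaging.
    """
    if samples.n_retained < 1:
        raise ValueError("no retained samples to summarise")
    S = samples.samples
    out: dict[str, float | np.ndarray] = {
        "S0": float(S[:, 0].mean()),
        "d": float(S[:, 1].mean()),
    }
    L = (S.shape[1] - 2) // 3
    for j in range(L):
        out[f"f{j + 1}"] = float(S[:, 2 + 3 * j].mean())
        dirs = _orientation_samples(S, j)
        dyad, disp = dyadic_mean(dirs)
        out[f"dyad{j + 1}"] = dyad
        out[f"dispersion{j + 1}"] = disp
    return out


def _orientation_samples(S: np.ndarray, j: int) -> np.ndarray:
    theta = S[:, 3 + 3 * j]
    phi = S[:, 4 + 3 * j]
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def dyadic_mean(vectors: np.ndarray) -> tuple[np.ndarray, float]:
    """Axial mean of orientation samples.

    Returns the principal eigenvector (sign chosen with non-negative z;
    axial data have no sign) and the largest eigenvalue of the mean
    outer-product tensor, the dispersion in [1/3, 1] (up to numerical
    round-off for nearly isotropic samples).
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.shape[0] < 1 or v.shape[1] != 3:
        raise ValueError("need at least one 3-vector")
    T = (v.T @ v) / v.shape[0]
    evals, evecs = np.linalg.eigh(T)
    dyad = evecs[:, -1]
    if dyad[2] < 0 or (dyad[2] == 0 and dyad[np.argmax(np.abs(dyad))] < 0):
        dyad = -dyad
    return dyad, float(evals[-1])


def angular_error(u: np.ndarray, v: np.ndarray) -> float:
    """Axial angle between two directions, in degrees within [0, 90]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = abs(float(u @ v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def paired_angular_errors(
    estimated: Sequence[np.ndarray], truth: Sequence[np.ndarray]
) -> np.ndarray:
    """Angular errors under the total-error-minimising stick assignment.

    With several sticks the estimate order is arbitrary; errors are
    computed after matching estimated dyads to ground-truth directions by
    minimum-cost assignment.
    """
    from scipy.optimize import linear_sum_assignment

    cost = np.array([[angular_error(e, t) for t in truth] for e in estimated])
    rows, cols = linear_sum_assignment(cost)
    return cost[rows, cols]


# ---------------------------------------------------------------------------
# repeated-execution validation between two engines

#: an engine maps (data, scheme, L, mcmc options, seed list) to a list of
#: posterior-mean dicts, one per seed
VoxelEngine = Callable[..., list]


def repeat_validation(
    data: np.ndarray,
    scheme,
    L: int,
    opts,
    n_repeats: int,
    engines: tuple[VoxelEngine, VoxelEngine],
    base_seed: int = 0,
    shared_seeds: bool = False,
) -> dict:
    """Compare two execution engines by their posterior-mean distributions.

    Each engine fits the same voxel ``n_repeats`` times; for every model
    parameter the two engines' distributions of posterior means are
    compared with a two-sample Kolmogorov-Smirnov test.  By default the
    engines draw disjoint seed blocks, so matching engines differ only by
    Monte Carlo noise and give large p-values, while a systematically
    different sampler is flagged by a small one.  With ``shared_seeds``
    both engines see identical seed lists (useful for exact-equivalence
    checks, where the KS statistic collapses to zero).
    """
    if n_repeats < 20:
        raise ValueError("need at least 20 repeats for a meaningful comparison")
    per_engine: list[dict[str, list[float]]] = []
    for ei, eng in enumerate(engines):
        offset = 0 if shared_seeds else ei * n_repeats
        seeds = [base_seed + offset + r for r in range(n_repeats)]
        cols: dict[str, list[float]] = {}
        for means in eng(data, scheme, L, opts, seeds):
            for name, val in _scalarise(means, L).items():
                cols.setdefault(name, []).append(val)
        per_engine.append(cols)

    report: dict[str, dict[str, float]] = {}
    for name in per_engine[0]:
        a = np.array(per_engine[0][name])
        b = np.array(per_engine[1][name])
        if np.array_equal(a, b):
            stat, p = 0.0, 1.0  # identical distributions
        else:
            res = ks_2samp(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        report[name] = {"ks_statistic": stat, "p_value": p}
    return report


def _scalarise(means: dict, L: int) -> dict[str, float]:
    """Flatten a posterior-mean dict to one scalar per model parameter.

    The two orientation parameters of each stick are represented by the
    polar and azimuthal angles of the dyadic mean (hemisphere-canonical).
    """
    out = {"S0": means["S0"], "d": means["d"]}
    for j in range(1, L + 1):
        out[f"f{j}"] = means[f"f{j}"]
        dyad = means[f"dyad{j}"]
        out[f"dyad{j}_theta"] = float(np.arccos(np.clip(abs(dyad[2]), -1, 1)))
        out[f"dyad{j}_phi"] = float(np.arctan2(dyad[1], dyad[0]))
    return out


def truth_direction(theta: float, phi: float) -> np.ndarray:
    """Convenience: ground-truth stick direction for summary comparisons."""
    return stick_direction(theta, phi)
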