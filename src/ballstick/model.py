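"""Ball & stick forward model: signal prediction, residuals and derivatives.

The voxel signal along a diffusion-sensitising gradient ``r_i`` with
b-value ``b_i`` is modelled as one isotropic compartment (the *ball*) plus
``L`` perfectly anisotropic compartments (the *sticks*)::

    S_i = S0 * [ (1 - sum_j f_j) * exp(-b_i d)
                 + sum_j f_j * exp(-b_i d (r_i . x_j)^2) ]

where ``S0`` is the non-diffusion-weighted baseline, ``d`` the diffusivity
(mm^2/s), ``f_j`` the volume fraction of stick ``j`` and
``x_j = (sin t cos p, sin t sin p, cos t)`` its orientation.  The signal
depends on ``x_j`` only through ``(r . x)^2``, so orientations are axial
(antipodally symmetric) quantities.

Everything here is pure computation on numpy arrays; file formats live in
:mod:`ballstick.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "BallStickParams",
    "stick_direction",
    "predict_signal",
    "residuals",
    "sum_sq",
    "jacobian",
]

#: b-values below this (s/mm^2) are treated as unweighted measurements.
B0_THRESHOLD = 50.0


@dataclass(frozen=True)
class AcquisitionScheme:
    """Measurement design: b-values, gradient directions and b=0 flags.

    Parameters
    ----------
    bvals : (K,) array
        Diffusion weightings in s/mm^2; non-negative.
    bvecs : (K, 3) array
        Unit gradient directions for the diffusion-weighted measurements.
        Rows flagged as b=0 may be zero vectors.
    b0_mask : (K,) bool array, optional
        Which measurements are unweighted.  Defaults to ``bvals < 50``.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (K, 3), got {bvecs.shape}")
        if bvals.shape != (bvecs.shape[0],):
            raise ValueError(
                f"bvals length {bvals.shape} does not match bvecs {bvecs.shape}"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        b0 = self.b0_mask
        if b0 is None:
            b0 = bvals < B0_THRESHOLD
        b0 = np.asarray(b0, dtype=bool)
        if b0.shape != bvals.shape:
            raise ValueError("b0_mask length mismatch")
        norms = np.linalg.norm(bvecs[~b0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-b0 gradient directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "b0_mask", b0)

    @property
    def n_measurements(self) -> int:
        return self.bvals.shape[0]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_measurements


@dataclass
class BallStickParams:
    """One voxel's model parameters.

    ``f``, ``theta`` and ``phi`` are per-stick arrays of common length L.
    The parameter count of the model is R = 3L + 2 (S0, d, and per-stick
    volume fraction and two spherical angles).
    """

    S0: float
    d: float
    f: np.ndarray
    theta: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if not (self.f.shape == self.theta.shape == self.phi.shape):
            raise ValueError("f, theta, phi must have equal length")
        if self.f.size < 1:
            raise ValueError("at least one stick is required (L >= 1)")

    @property
    def n_sticks(self) -> int:
        return self.f.size

    @property
    def n_params(self) -> int:
        return 3 * self.n_sticks + 2

    def validate(self) -> None:
        """Raise if the parameters violate the model constraints."""
        if self.S0 < 0 or self.d < 0:
            raise ValueError("S0 and d must be non-negative")
        if np.any(self.f < 0) or np.any(self.f > 1) or self.f.sum() > 1:
            raise ValueError("volume fractions must lie in the unit simplex")

    # -- flat vector layout: [S0, d, f1, th1, ph1, f2, th2, ph2, ...] ------
    # This fixed order is also the MCMC update order and the index layout
    # of pre-generated random streams; do not change it.
    def to_vector(self) -> np.ndarray:
        L = self.n_sticks
        v = np.empty(2 + 3 * L)
        v[0] = self.S0
        v[1] = self.d
        v[2::3] = self.f
        v[3::3] = self.theta
        v[4::3] = self.phi
        return v

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "BallStickParams":
        v = np.asarray(v, dtype=float)
        if (v.size - 2) % 3 != 0 or v.size < 5:
            raise ValueError(f"parameter vector length {v.size} is not 3L+2")
        return cls(S0=v[0], d=v[1], f=v[2::3], theta=v[3::3], phi=v[4::3])


def param_names(L: int) -> list[str]:
    """Parameter names in flat-vector (and MCMC update) order."""
    names = ["S0", "d"]
    for j in range(1, L + 1):
        names += [f"f{j}", f"theta{j}", f"phi{j}"]
    return names


def stick_direction(theta: float, phi: float) -> np.ndarray:
    """Unit vector (sin t cos p, sin t sin p, cos t) for spherical angles."""
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _check_data(data: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.shape != (scheme.n_measurements,):
        raise ValueError(
            f"data length {data.shape} does not match scheme "
            f"({scheme.n_measurements} measurements)"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    return data


def predict_signal(params: BallStickParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Forward ball & stick signal for every measurement in the scheme.

    The per-stick terms are accumulated in stick order with explicit
    elementwise operations so that the batched engine can reproduce the
    same floating-point result (see :mod:`ballstick.engine`).
    """
    b = scheme.bvals
    g = scheme.bvecs
    ball = np.exp(-b * params.d)
    ftot = 0.0
    aniso = np.zeros_like(b)
    for j in range(params.n_sticks):
        x = stick_direction(params.theta[j], params.phi[j])
        dot = g[:, 0] * x[0] + g[:, 1] * x[1] + g[:, 2] * x[2]
        aniso = aniso + params.f[j] * np.exp(-b * params.d * (dot * dot))
        ftot += params.f[j]
    return params.S0 * ((1.0 - ftot) * ball + aniso)


def residuals(
    params: BallStickParams, scheme: AcquisitionScheme, data: np.ndarray
) -> np.ndarray:
    """data minus model prediction."""
    data = _check_data(data, scheme)
    return data - predict_signal(params, scheme)


def sum_sq(r: np.ndarray) -> float:
    """Sum of squared residuals with a fixed reduction order.

    Both execution engines funnel their residual reductions through this
    single function so that serial and batched runs are bitwise comparable.
    """
    r = np.ascontiguousarray(r, dtype=float)
    return float(np.dot(r, r))


def jacobian(params: BallStickParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Analytic K x R sensitivity matrix dS_i/dp.

    Columns follow the flat vector layout ``[S0, d, f1, th1, ph1, ...]``.
    Matches central finite differences to ~1e-4 relative at interior points.
    """
    b = scheme.bvals
    g = scheme.bvecs
    K = scheme.n_measurements
    L = params.n_sticks
    J = np.zeros((K, 2 + 3 * L))

    ball = np.exp(-b * params.d)
    ftot = params.f.sum()
    model_over_S0 = (1.0 - ftot) * ball
    dS_dd = params.S0 * (1.0 - ftot) * (-b) * ball

    for j in range(L):
        st, ct = np.sin(params.theta[j]), np.cos(params.theta[j])
        sp, cp = np.sin(params.phi[j]), np.cos(params.phi[j])
        x = np.array([st * cp, st * sp, ct])
        dot = g @ x
        att = np.exp(-b * params.d * dot**2)
        model_over_S0 = model_over_S0 + params.f[j] * att
        dS_dd = dS_dd + params.S0 * params.f[j] * (-b * dot**2) * att
        # dS/df_j: stick term replaces ball term
        J[:, 2 + 3 * j] = params.S0 * (att - ball)
        # d(dot)/dtheta and d(dot)/dphi via the spherical parameterisation
        dx_dth = np.array([ct * cp, ct * sp, -st])
        dx_dph = np.array([-st * sp, st * cp, 0.0])
        common = params.S0 * params.f[j] * att * (-2.0 * b * params.d * dot)
        J[:, 3 + 3 * j] = common * (g @ dx_dth)
        J[:, 4 + 3 * j] = common * (g @ dx_dph)

    J[:, 0] = model_over_S0
    J[:, 1] = dS_dd
    return J
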