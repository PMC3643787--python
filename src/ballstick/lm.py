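"""Stage 1: deterministic Levenberg-Marquardt fit seeding the MCMC.

The fit runs in a transformed, unconstrained space — ``S0 = s^2``,
``d = u^2`` keep the non-negativity constraints, ``f_j = sin^2(w_j)``
keeps each volume fraction in [0, 1], angles are free — and the simplex
constraint ``sum f_j <= 1`` is enforced by projecting each candidate
before it is evaluated.  A candidate step is accepted only if its
(projected) sum of squared residuals is strictly lower than the current
one, so the accepted trace is monotone non-increasing by construction.
There is no randomness anywhere in this stage: identical inputs give
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    AcquisitionScheme,
    BallStickParams,
    jacobian,
    predict_signal,
    sum_sq,
)

__all__ = ["LMOptions", "LMResult", "init_guess", "lm_fit"]


@dataclass(frozen=True)
class LMOptions:
    """Damped least-squares controls.

    ftol is the relative sum-of-squares improvement below which the fit
    stops; the damping schedule is the classic x10 / x0.1 ladder.
    """

    max_iter: int = 200
    ftol: float = 1e-9
    initial_lambda: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 0.1

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.ftol <= 0:
            raise ValueError("ftol must be positive")
        if self.lambda_up <= 1 or not (0 < self.lambda_down < 1):
            raise ValueError("need lambda_up > 1 and 0 < lambda_down < 1")


@dataclass
class LMResult:
    params: BallStickParams
    iterations: int
    final_sum_sq: float
    converged: bool
    sum_sq_trace: list[float]


class InitializationError(ValueError):
    """Raised when the data cannot seed a fit (e.g. no b=0 volumes)."""


# ---------------------------------------------------------------------------
# initial guess from a log-linear diffusion tensor fit


def init_guess(data: np.ndarray, scheme: AcquisitionScheme, L: int) -> BallStickParams:
    """Seed parameters from a log-linear diffusion-tensor fit.

    S0 is the mean unweighted signal; d the mean tensor eigenvalue; the
    first stick takes the principal eigenvector with f1 set from the
    fractional anisotropy (clipped to [0.01, 0.95]); additional sticks
    take the remaining eigenvectors with f_j = f1 / (j + 1).
    """
    data = np.asarray(data, dtype=float)
    b0 = scheme.b0_mask
    if not b0.any():
        raise InitializationError("initialization requires at least one b=0 volume")
    n_dwi = int((~b0).sum())
    if n_dwi < 6:
        raise InitializationError(
            f"initialization requires >= 6 diffusion-weighted volumes, got {n_dwi}"
        )
    S0 = float(data[b0].mean())
    if S0 <= 0:
        raise InitializationError("mean b=0 signal is non-positive")

    b = scheme.bvals[~b0]
    g = scheme.bvecs[~b0]
    s = np.clip(data[~b0], 1e-10 * S0, None)
    y = np.log(s / S0)
    # design for the 6 unique tensor components, log S/S0 = -b g' D g
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    B = -b[:, None] * np.column_stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )
    try:
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        D = np.array(
            [
                [coef[0], coef[3], coef[4]],
                [coef[3], coef[1], coef[5]],
                [coef[4], coef[5], coef[2]],
            ]
        )
        evals, evecs = np.linalg.eigh(D)  # ascending
        if not np.all(np.isfinite(evals)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return _isotropic_init(S0, b, s, L)

    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    d = float(np.clip(evals.mean(), 1e-6, None))
    # fractional anisotropy of the (possibly non-SPD) fitted tensor
    lam = np.clip(evals, 0.0, None)
    denom = float(np.sqrt((lam**2).sum()))
    if denom <= 0:
        return _isotropic_init(S0, b, s, L)
    fa = float(np.sqrt(1.5 * ((lam - lam.mean()) ** 2).sum()) / denom)
    f1 = float(np.clip(fa, 0.01, 0.95))

    f = np.empty(L)
    theta = np.empty(L)
    phi = np.empty(L)
    for j in range(L):
        v = evecs[:, min(j, 2)]
        theta[j] = np.arccos(np.clip(v[2], -1.0, 1.0))
        phi[j] = np.arctan2(v[1], v[0])
        f[j] = f1 if j == 0 else f1 / (j + 2)  # f_j = f1/(j+1) with 1-based j
    if f.sum() > 0.99:
        f *= 0.99 / f.sum()
    return BallStickParams(S0=S0, d=d, f=f, theta=theta, phi=phi)


def _isotropic_init(
    S0: float, b: np.ndarray, s: np.ndarray, L: int
) -> BallStickParams:
    """Fallback when the tensor system is singular: small isotropic sticks
    along the coordinate axes, d from the median apparent diffusion."""
    adc = -np.log(np.clip(s / S0, 1e-10, None)) / np.clip(b, 1.0, None)
    d = float(np.clip(np.median(adc), 1e-5, None))
    axes = np.eye(3)
    theta = np.array([np.arccos(axes[min(j, 2), 2]) for j in range(L)])
    phi = np.array([np.arctan2(axes[min(j, 2), 1], axes[min(j, 2), 0]) for j in range(L)])
    return BallStickParams(S0=S0, d=d, f=np.full(L, 0.05), theta=theta, phi=phi)


# ---------------------------------------------------------------------------
# constraint transforms


def _to_internal(p: BallStickParams) -> np.ndarray:
    L = p.n_sticks
    x = np.empty(2 + 3 * L)
    x[0] = np.sqrt(max(p.S0, 0.0))
    x[1] = np.sqrt(max(p.d, 0.0))
    x[2::3] = np.arcsin(np.sqrt(np.clip(p.f, 0.0, 1.0)))
    x[3::3] = p.theta
    x[4::3] = p.phi
    return x


def _from_internal(x: np.ndarray) -> BallStickParams:
    return BallStickParams(
        S0=x[0] ** 2,
        d=x[1] ** 2,
        f=np.sin(x[2::3]) ** 2,
        theta=x[3::3],
        phi=x[4::3],
    )


def _project_simplex(p: BallStickParams) -> BallStickParams:
    ftot = p.f.sum()
    if ftot > 1.0:
        p = BallStickParams(
            S0=p.S0, d=p.d, f=p.f * (1.0 - 1e-9) / ftot, theta=p.theta, phi=p.phi
        )
    return p


def _internal_jacobian(x: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Chain rule: J wrt internal coordinates from the analytic natural J."""
    p = _from_internal(x)
    J = jacobian(p, scheme)
    scale = np.ones_like(x)
    scale[0] = 2.0 * x[0]
    scale[1] = 2.0 * x[1]
    scale[2::3] = 2.0 * np.sin(x[2::3]) * np.cos(x[2::3])
    return J * scale[None, :]


# ---------------------------------------------------------------------------


def lm_fit(
    data: np.ndarray,
    scheme: AcquisitionScheme,
    L: int,
    opts: LMOptions | None = None,
    init: BallStickParams | None = None,
) -> LMResult:
    """Levenberg-Marquardt fit of the ball & stick model to one voxel.

    Returns the constrained parameter estimate together with the number
    of damping cycles used, the final sum of squared residuals, a
    convergence flag, and the accepted sum_sq trace (non-increasing).
    """
    if opts is None:
        opts = LMOptions()
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    if init is None:
        init = init_guess(data, scheme, L)

    x = _to_internal(_project_simplex(init))
    cur = _from_internal(x)
    ss = sum_sq(data - predict_signal(cur, scheme))
    trace = [ss]
    lam = opts.initial_lambda
    # machine-precision fit: nothing left to gain
    ss_floor = max(1e-300, 1e-20 * sum_sq(data))
    converged = ss <= ss_floor
    it = 0

    for it in range(1, opts.max_iter + 1):
        if converged:
            break
        r = data - predict_signal(cur, scheme)
        J = _internal_jacobian(x, scheme)
        JtJ = J.T @ J
        Jtr = J.T @ r
        diag = np.diag(JtJ).copy()
        diag[diag <= 0] = 1e-12
        try:
            step = np.linalg.solve(JtJ + lam * np.diag(diag), Jtr)
        except np.linalg.LinAlgError:
            lam *= opts.lambda_up
            continue
        x_new = x + step
        cand = _project_simplex(_from_internal(x_new))
        ss_new = sum_sq(data - predict_signal(cand, scheme))
        if np.isfinite(ss_new) and ss_new < ss:
            rel_impr = (ss - ss_new) / max(ss, 1e-300)
            x = _to_internal(cand)
            cur = cand
            ss = ss_new
            trace.append(ss)
            lam = max(lam * opts.lambda_down, 1e-12)
            if rel_impr < opts.ftol or ss <= ss_floor:
                converged = True
                break
        else:
            if np.isfinite(ss_new) and abs(ss_new - ss) / max(ss, 1e-300) < opts.ftol:
                converged = True  # no meaningful improvement available
                break
            lam *= opts.lambda_up
            if lam > 1e12:
                converged = True  # damping exhausted: at a (local) minimum
                break

    cur.validate()
    return LMResult(
        params=cur,
        iterations=it,
        final_sum_sq=ss,
        converged=converged,
        sum_sq_trace=trace,
    )
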