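"""Stage 2: random-walk Metropolis sampling of the per-voxel posterior.

The noise variance of the Gaussian likelihood is marginalised
analytically under a noninformative prior, leaving

    log L(params | data) = -(K/2) * log( SSR(params) )

with SSR the sum of squared residuals (floored at 1e-12).  Priors are
flat on S0 >= 0 and d >= 0, flat on the volume-fraction simplex
(f_j in [0,1], sum f_j <= 1), and uniform-on-the-sphere for each stick
orientation, i.e. a density proportional to |sin theta| in the spherical
angles (the model is antipodally symmetric, so the absolute value keeps
the axial density correct for angles wrapped beyond (0, pi)).

Parameters are updated one at a time, in the fixed order
``S0, d, (f1, theta1, phi1), (f2, theta2, phi2), ...`` — the same order
that indexes the pre-generated random streams.  All Normal and Uniform
draws a chain will need are generated up front (one of each per
iteration and parameter), so a chain is a pure function of its inputs:
reruns with the same :class:`RandomStream` are bitwise identical, and
the serial and batched engines can be compared draw for draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import (
    AcquisitionScheme,
    BallStickParams,
    predict_signal,
    sum_sq,
)

__all__ = [
    "MCMCOptions",
    "RandomStream",
    "PosteriorSamples",
    "log_prior",
    "log_marginal_likelihood",
    "metropolis_update",
    "run_mcmc",
    "generate_stream",
    "metropolis_chain",
]

SSR_FLOOR = 1e-12

#: adaptation window length (iterations) during burn-in
ADAPT_EVERY = 40
#: per-window multiplicative clip on proposal-sd updates
ADAPT_CLIP = (0.5, 2.0)
#: adaptation targets this acceptance fraction
ADAPT_TARGET = 0.5


@dataclass(frozen=True)
class MCMCOptions:
    """Chain length controls.

    burnin iterations are discarded (with optional proposal adaptation),
    then njumps iterations are run with every sampleevery-th state
    retained: floor(njumps / sampleevery) samples per parameter.
    """

    burnin: int = 3000
    njumps: int = 1250
    sampleevery: int = 25
    proposal_sds: np.ndarray | None = None
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.burnin < 0 or self.njumps < 0:
            raise ValueError("burnin and njumps must be non-negative")
        if self.sampleevery < 1:
            raise ValueError("sampleevery must be >= 1")

    @property
    def n_iterations(self) -> int:
        return self.burnin + self.njumps

    @property
    def n_retained(self) -> int:
        return self.njumps // self.sampleevery


@dataclass(frozen=True)
class RandomStream:
    """Pre-generated Normal and Uniform draws indexed (iteration, parameter)."""

    seed: int
    normals: np.ndarray
    uniforms: np.ndarray

    def __post_init__(self) -> None:
        if self.normals.shape != self.uniforms.shape or self.normals.ndim != 2:
            raise ValueError("normals and uniforms must share a (T, R) shape")

    @property
    def n_iterations(self) -> int:
        return self.normals.shape[0]

    @property
    def n_params(self) -> int:
        return self.normals.shape[1]


@dataclass
class PosteriorSamples:
    """Retained post-burn-in, thinned samples for one voxel."""

    samples: np.ndarray  # (n_retained, R) in flat vector order
    accept_counts: np.ndarray  # (R,) over post-burn-in iterations
    n_post_iterations: int
    final_state: np.ndarray  # (R,)
    param_names: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.samples.shape[0]

    def acceptance_fraction(self) -> np.ndarray:
        return self.accept_counts / max(self.n_post_iterations, 1)


def generate_stream(seed: int, opts: MCMCOptions, R: int) -> RandomStream:
    """Fill Normal and Uniform buffers of shape (burnin+njumps, R) from PCG64."""
    T = opts.n_iterations
    rng = np.random.default_rng(seed)
    normals = rng.standard_normal((T, R))
    uniforms = rng.random((T, R))
    return RandomStream(seed=seed, normals=normals, uniforms=uniforms)


# ---------------------------------------------------------------------------
# posterior pieces


def log_prior(params: BallStickParams) -> float:
    """Log prior density; -inf outside the support."""
    if params.S0 < 0 or params.d < 0:
        return -np.inf
    f = params.f
    if np.any(f < 0) or np.any(f > 1) or f.sum() > 1:
        return -np.inf
    s = np.abs(np.sin(params.theta))
    if np.any(s == 0):
        return -np.inf
    out = 0.0
    for v in np.log(s):  # fixed accumulation order, matches batched engine
        out += v
    return out


def log_marginal_likelihood(
    params: BallStickParams, data: np.ndarray, scheme: AcquisitionScheme
) -> float:
    """Gaussian log likelihood with the noise variance integrated out."""
    data = np.asarray(data, dtype=float)
    if data.shape != (scheme.n_measurements,):
        raise ValueError("data length does not match scheme")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    if scheme.n_measurements < 2:
        raise ValueError("need at least two measurements")
    ssr = sum_sq(data - predict_signal(params, scheme))
    return -0.5 * scheme.n_measurements * np.log(max(ssr, SSR_FLOOR))


def _log_posterior(
    x: np.ndarray, data: np.ndarray, scheme: AcquisitionScheme
) -> float:
    p = BallStickParams.from_vector(x)
    lp = log_prior(p)
    if lp == -np.inf:
        return -np.inf
    return lp + log_marginal_likelihood(p, data, scheme)


# ---------------------------------------------------------------------------
# updates


@dataclass
class ChainState:
    """Current position and cached log posterior of one chain."""

    x: np.ndarray
    log_post: float


def metropolis_update(
    state: ChainState,
    param_index: int,
    normal_draw: float,
    uniform_draw: float,
    proposal_sd: float,
    log_post_fn: Callable[[np.ndarray], float],
) -> bool:
    """One single-parameter random-walk Metropolis step, in place.

    Consumes exactly the two supplied draws.  Returns True on acceptance.
    """
    old = state.x[param_index]
    state.x[param_index] = old + proposal_sd * normal_draw
    lp_new = log_post_fn(state.x)
    delta = lp_new - state.log_post
    with np.errstate(divide="ignore"):
        if np.log(uniform_draw) < delta:
            state.log_post = lp_new
            return True
    state.x[param_index] = old
    return False


def metropolis_chain(
    log_post_fn: Callable[[np.ndarray], float],
    x0: Sequence[float],
    opts: MCMCOptions,
    stream: RandomStream,
    names: list[str] | None = None,
) -> PosteriorSamples:
    """Generic component-wise random-walk Metropolis sampler.

    Used both for the ball & stick posterior (via :func:`run_mcmc`) and,
    with a user-supplied target, for sampler-correctness checks on
    tractable distributions.
    """
    x = np.array(x0, dtype=float)
    R = x.size
    if stream.n_params != R:
        raise ValueError(f"stream has {stream.n_params} parameters, state has {R}")
    if stream.n_iterations < opts.n_iterations:
        raise ValueError(
            f"stream too short: {stream.n_iterations} < {opts.n_iterations} iterations"
        )

    sds = (
        np.array(opts.proposal_sds, dtype=float)
        if opts.proposal_sds is not None
        else _default_proposal_sds(x)
    )
    if sds.shape != (R,):
        raise ValueError("proposal_sds must have one entry per parameter")

    state = ChainState(x=x, log_post=log_post_fn(x))
    if state.log_post == -np.inf:
        raise ValueError("initial state outside prior support")

    n_keep = opts.n_retained
    samples = np.empty((n_keep, R))
    accept_post = np.zeros(R, dtype=int)
    adapt_acc = np.zeros(R, dtype=int)
    kept = 0

    for t in range(opts.n_iterations):
        in_burnin = t < opts.burnin
        for p in range(R):
            accepted = metropolis_update(
                state,
                p,
                stream.normals[t, p],
                stream.uniforms[t, p],
                sds[p],
                log_post_fn,
            )
            if accepted:
                if in_burnin:
                    adapt_acc[p] += 1
                else:
                    accept_post[p] += 1
        if in_burnin and opts.adapt and (t + 1) % ADAPT_EVERY == 0:
            frac = adapt_acc / ADAPT_EVERY
            sds = sds * np.clip(frac / ADAPT_TARGET, *ADAPT_CLIP)
            adapt_acc[:] = 0
        if not in_burnin:
            t_post = t - opts.burnin + 1
            if t_post % opts.sampleevery == 0 and kept < n_keep:
                samples[kept] = state.x
                kept += 1

    return PosteriorSamples(
        samples=samples[:kept],
        accept_counts=accept_post,
        n_post_iterations=opts.njumps,
        final_state=state.x.copy(),
        param_names=names or [f"p{i}" for i in range(R)],
    )


def _default_proposal_sds(x0: np.ndarray) -> np.ndarray:
    """Scale-aware defaults; burn-in adaptation refines them."""
    sds = np.full(x0.size, 0.1)
    sds[0] = max(0.05 * abs(x0[0]), 1e-3)  # S0
    if x0.size >= 2:
        sds[1] = max(0.1 * abs(x0[1]), 1e-5)  # d
    for j in range(2, x0.size, 3):
        sds[j] = 0.05  # f
    return sds


def run_mcmc(
    data: np.ndarray,
    scheme: AcquisitionScheme,
    init: BallStickParams,
    opts: MCMCOptions,
    stream: RandomStream,
    log_prior_fn: Callable[[BallStickParams], float] | None = None,
) -> PosteriorSamples:
    """Sample the ball & stick posterior of one voxel.

    init is projected slightly into the interior of the prior support if
    the LM stage left it on a boundary.  log_prior_fn is a test hook
    replacing the default prior (used e.g. by negative-control checks).
    """
    from .model import param_names

    data = np.asarray(data, dtype=float)
    init = project_into_support(init)
    if log_prior_fn is None:
        log_post = lambda x: _log_posterior(x, data, scheme)  # noqa: E731
    else:
        def log_post(x: np.ndarray) -> float:
            p = BallStickParams.from_vector(x)
            lp = log_prior_fn(p)
            if lp == -np.inf:
                return -np.inf
            return lp + log_marginal_likelihood(p, data, scheme)

    return metropolis_chain(
        log_post,
        init.to_vector(),
        opts,
        stream,
        names=param_names(init.n_sticks),
    )


def project_into_support(p: BallStickParams, eps: float = 1e-6) -> BallStickParams:
    """Nudge boundary parameters strictly inside the prior support."""
    f = np.clip(p.f, eps, 1.0 - eps)
    if f.sum() > 1.0 - eps:
        f = f * (1.0 - eps) / f.sum()
    theta = p.theta.copy()
    near_pole = np.abs(np.sin(theta)) < eps
    theta[near_pole] += eps
    return BallStickParams(
        S0=max(p.S0, eps),
        d=max(p.d, eps * 1e-3),
        f=f,
        theta=theta,
        phi=p.phi.copy(),
    )
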