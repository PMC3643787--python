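"""Volume-level execution: serial reference and batched data-parallel engines.

The decomposition mirrors a GPU-style design in numpy terms:

* the deterministic LM stage is data-parallel over voxels (each voxel is
  an independent scalar fit, grouped into batches);
* the MCMC stage runs one chain per voxel, with many voxels advanced in
  lock-step by vectorising the proposal, the K signal evaluations and the
  accept/reject bookkeeping across the batch;
* slices (third spatial axis) are partitioned across workers that share
  nothing mid-run.

Every voxel consumes its own pre-generated :class:`~ballstick.mcmc.RandomStream`
whose seed is derived from ``base_seed`` plus the voxel's linear index, so
the batched engine and the serial reference visit *identical* random
numbers.  All floating-point operations are ordered identically in the two
engines (residual reductions go through :func:`ballstick.model.sum_sq` on
contiguous per-voxel vectors), so their chains agree bitwise; results are
likewise invariant to ``batch_size`` and ``workers``, which only regroup
independent work.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from joblib import Parallel, delayed

from .lm import LMOptions, lm_fit
from .mcmc import (
    ADAPT_CLIP,
    ADAPT_EVERY,
    ADAPT_TARGET,
    MCMCOptions,
    PosteriorSamples,
    RandomStream,
    SSR_FLOOR,
    _default_proposal_sds,
    generate_stream,
    project_into_support,
    run_mcmc,
)
from .model import AcquisitionScheme, BallStickParams, param_names, sum_sq
from .summaries import VolumeResult, posterior_means

__all__ = [
    "BatchOptions",
    "fit_volume",
    "fit_voxel",
    "partition_slices",
    "run_mcmc_batch",
    "serial_voxel_engine",
    "batched_voxel_engine",
]


@dataclass(frozen=True)
class BatchOptions:
    """Execution layout knobs with no effect on results.

    batch_size is the number of voxels advanced in lock-step by the
    batched MCMC kernel (64 by default, a good batch width for this kind
    of voxelwise workload); workers is the number of parallel slice
    processors; base_seed anchors the per-voxel stream seeds
    (``base_seed + linear voxel index``).
    """

    batch_size: int = 64
    workers: int = 1
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.workers < 1:
            raise ValueError("batch_size and workers must be >= 1")


# ---------------------------------------------------------------------------
# slice partitioning


def partition_slices(mask: np.ndarray, workers: int) -> list[list[int]]:
    """Assign slice indices (third axis) to workers, balanced by voxel count.

    Greedy largest-first: slices are sorted by masked-voxel count and each
    is given to the currently lightest worker.  Slices without masked
    voxels are dropped.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    counts = mask.reshape(-1, mask.shape[2]).sum(axis=0)
    order = [int(z) for z in np.argsort(counts)[::-1] if counts[z] > 0]
    loads = [0] * workers
    assignment: list[list[int]] = [[] for _ in range(workers)]
    for z in order:
        w = int(np.argmin(loads))
        assignment[w].append(z)
        loads[w] += int(counts[z])
    return assignment


# ---------------------------------------------------------------------------
# batched MCMC kernel


def run_mcmc_batch(
    data: np.ndarray,
    scheme: AcquisitionScheme,
    inits: list[BallStickParams],
    opts: MCMCOptions,
    streams: list[RandomStream],
) -> list[PosteriorSamples]:
    """Advance one Metropolis chain per voxel in lock-step.

    Vectorises the per-iteration work (proposal, the K signal
    evaluations, prior support checks, accept/reject) across the V voxels
    of the batch while keeping the per-voxel arithmetic identical to
    :func:`ballstick.mcmc.run_mcmc`: same update order, same random draws,
    same reduction order for the residual sum of squares.
    """
    V = len(inits)
    if V == 0:
        return []
    if len(streams) != V:
        raise ValueError("one RandomStream per voxel is required")
    L = inits[0].n_sticks
    R = 2 + 3 * L
    T = opts.n_iterations
    for s in streams:
        if s.n_params != R or s.n_iterations < T:
            raise ValueError("stream shape does not match options/model")

    data = np.ascontiguousarray(np.asarray(data, dtype=float))
    if data.shape != (V, scheme.n_measurements):
        raise ValueError("data must be (V, K)")

    b = scheme.bvals
    g = scheme.bvecs
    K = scheme.n_measurements
    g0, g1, g2 = g[:, 0], g[:, 1], g[:, 2]

    X = np.stack([project_into_support(p).to_vector() for p in inits])  # (V, R)
    normals = np.stack([s.normals[:T] for s in streams])  # (V, T, R)
    uniforms = np.stack([s.uniforms[:T] for s in streams])

    if opts.proposal_sds is not None:
        sds = np.tile(np.asarray(opts.proposal_sds, dtype=float), (V, 1))
    else:
        sds = np.stack([_default_proposal_sds(X[v]) for v in range(V)])

    def log_post(Xc: np.ndarray) -> np.ndarray:
        """Vectorised log posterior; -inf outside the prior support."""
        S0 = Xc[:, 0]
        d = Xc[:, 1]
        f = Xc[:, 2::3]
        theta = Xc[:, 3::3]
        sin_t = np.abs(np.sin(theta))
        ftot = np.zeros(V)
        for j in range(L):
            ftot = ftot + f[:, j]
        valid = (
            (S0 >= 0)
            & (d >= 0)
            & np.all((f >= 0) & (f <= 1), axis=1)
            & (ftot <= 1)
            & np.all(sin_t > 0, axis=1)
        )
        with np.errstate(all="ignore"):
            lp = np.zeros(V)
            for j in range(L):
                lp = lp + np.log(sin_t[:, j])
            bd = (-b)[None, :] * d[:, None]  # (V, K)
            ball = np.exp(bd)
            ftot2 = np.zeros(V)
            aniso = np.zeros((V, K))
            for j in range(L):
                th = Xc[:, 3 + 3 * j]
                ph = Xc[:, 4 + 3 * j]
                st = np.sin(th)
                x0 = st * np.cos(ph)
                x1 = st * np.sin(ph)
                x2 = np.cos(th)
                dot = (
                    g0[None, :] * x0[:, None]
                    + g1[None, :] * x1[:, None]
                    + g2[None, :] * x2[:, None]
                )
                aniso = aniso + f[:, j][:, None] * np.exp(bd * (dot * dot))
                ftot2 = ftot2 + f[:, j]
            sig = S0[:, None] * ((1.0 - ftot2)[:, None] * ball + aniso)
            r = np.ascontiguousarray(data - sig)
            ssr = np.empty(V)
            for v in range(V):
                ssr[v] = sum_sq(r[v])
            ll = -0.5 * K * np.log(np.maximum(ssr, SSR_FLOOR))
            out = lp + ll
        return np.where(valid, out, -np.inf)

    cache = log_post(X)
    if np.any(cache == -np.inf):
        raise ValueError("an initial state lies outside the prior support")

    n_keep = opts.n_retained
    samples = np.empty((V, n_keep, R))
    accept_post = np.zeros((V, R), dtype=int)
    adapt_acc = np.zeros((V, R), dtype=int)
    kept = 0

    with np.errstate(divide="ignore"):
        log_u = np.log(uniforms)

    for t in range(T):
        in_burnin = t < opts.burnin
        for p in range(R):
            old = X[:, p].copy()
            X[:, p] = old + sds[:, p] * normals[:, t, p]
            lp_new = log_post(X)
            delta = lp_new - cache
            acc = log_u[:, t, p] < delta
            X[:, p] = np.where(acc, X[:, p], old)
            cache = np.where(acc, lp_new, cache)
            if in_burnin:
                adapt_acc[:, p] += acc
            else:
                accept_post[:, p] += acc
        if in_burnin and opts.adapt and (t + 1) % ADAPT_EVERY == 0:
            frac = adapt_acc / ADAPT_EVERY
            sds = sds * np.clip(frac / ADAPT_TARGET, *ADAPT_CLIP)
            adapt_acc[:] = 0
        if not in_burnin:
            t_post = t - opts.burnin + 1
            if t_post % opts.sampleevery == 0 and kept < n_keep:
                samples[:, kept, :] = X
                kept += 1

    names = param_names(L)
    return [
        PosteriorSamples(
            samples=samples[v, :kept],
            accept_counts=accept_post[v],
            n_post_iterations=opts.njumps,
            final_state=X[v].copy(),
            param_names=names,
        )
        for v in range(V)
    ]


# ---------------------------------------------------------------------------
# per-voxel pipeline and volume driver


def fit_voxel(
    data: np.ndarray,
    scheme: AcquisitionScheme,
    L: int,
    lm_opts: LMOptions | None,
    mcmc_opts: MCMCOptions,
    seed: int,
) -> PosteriorSamples:
    """Serial reference pipeline for one voxel: LM fit, then MCMC."""
    fit = lm_fit(data, scheme, L, lm_opts)
    stream = generate_stream(seed, mcmc_opts, fit.params.n_params)
    return run_mcmc(data, scheme, fit.params, mcmc_opts, stream)


def serial_voxel_engine(data, scheme, L, opts, seeds):
    """Engine adapter: serial chains, one per seed -> posterior means."""
    fit = lm_fit(data, scheme, L, None)
    out = []
    for seed in seeds:
        stream = generate_stream(seed, opts, fit.params.n_params)
        out.append(posterior_means(run_mcmc(data, scheme, fit.params, opts, stream)))
    return out


def batched_voxel_engine(data, scheme, L, opts, seeds):
    """Engine adapter: all repeats advanced in lock-step by the batched kernel."""
    data = np.asarray(data, dtype=float)
    fit = lm_fit(data, scheme, L, None)
    streams = [generate_stream(seed, opts, fit.params.n_params) for seed in seeds]
    res = run_mcmc_batch(
        np.tile(data, (len(seeds), 1)), scheme, [fit.params] * len(seeds), opts, streams
    )
    return [posterior_means(r) for r in res]


def _process_voxels(
    idx_list: list[tuple[int, int, int]],
    data4d: np.ndarray,
    scheme: AcquisitionScheme,
    L: int,
    lm_opts: LMOptions | None,
    mcmc_opts: MCMCOptions,
    batch_opts: BatchOptions,
    shape: tuple[int, int, int],
    engine: str,
) -> list[tuple[tuple[int, int, int], PosteriorSamples]]:
    out: list[tuple[tuple[int, int, int], PosteriorSamples]] = []
    for start in range(0, len(idx_list), batch_opts.batch_size):
        chunk = idx_list[start : start + batch_opts.batch_size]
        datas = [np.asarray(data4d[ijk], dtype=float) for ijk in chunk]
        seeds = [
            batch_opts.base_seed + int(np.ravel_multi_index(ijk, shape))
            for ijk in chunk
        ]
        if engine == "serial":
            for ijk, dat, seed in zip(chunk, datas, seeds):
                out.append((ijk, fit_voxel(dat, scheme, L, lm_opts, mcmc_opts, seed)))
        else:
            fits = [lm_fit(dat, scheme, L, lm_opts).params for dat in datas]
            streams = [
                generate_stream(seed, mcmc_opts, 2 + 3 * L) for seed in seeds
            ]
            results = run_mcmc_batch(np.stack(datas), scheme, fits, mcmc_opts, streams)
            out.extend(zip(chunk, results))
    return out


def fit_volume(
    data4d: np.ndarray,
    mask: np.ndarray,
    scheme: AcquisitionScheme,
    L: int = 1,
    lm_opts: LMOptions | None = None,
    mcmc_opts: MCMCOptions | None = None,
    batch_opts: BatchOptions | None = None,
    engine: str = "batched",
    keep_samples: bool = False,
) -> VolumeResult:
    """Fit the ball & stick model in every masked voxel of a 4D volume.

    Voxels are fully independent: each gets a deterministic random stream
    derived from ``batch_opts.base_seed`` and its linear index, so the
    result is invariant to the engine (``"batched"`` or ``"serial"``), to
    ``batch_size`` and to ``workers``.
    """
    if engine not in ("batched", "serial"):
        raise ValueError(f"unknown engine {engine!r}")
    if mcmc_opts is None:
        mcmc_opts = MCMCOptions()
    if batch_opts is None:
        batch_opts = BatchOptions()
    data4d = np.asarray(data4d, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if data4d.ndim != 4 or mask.shape != data4d.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} must match data spatial dims {data4d.shape[:3]}"
        )
    if data4d.shape[3] != scheme.n_measurements:
        raise ValueError(
            f"data has {data4d.shape[3]} volumes but scheme has "
            f"{scheme.n_measurements} measurements"
        )
    shape = mask.shape
    result = VolumeResult.empty(shape, mask, L)
    if not mask.any():
        warnings.warn("mask is empty: returning all-zero maps", stacklevel=2)
        return result

    assignment = partition_slices(mask, batch_opts.workers)

    def slice_voxels(zs: list[int]) -> list[tuple[int, int, int]]:
        idx = []
        for z in sorted(zs):
            ii, jj = np.nonzero(mask[:, :, z])
            idx.extend((int(i), int(j), int(z)) for i, j in zip(ii, jj))
        return idx

    jobs = [slice_voxels(zs) for zs in assignment if zs]
    if batch_opts.workers == 1 or len(jobs) <= 1:
        chunks = [
            _process_voxels(
                j, data4d, scheme, L, lm_opts, mcmc_opts, batch_opts, shape, engine
            )
            for j in jobs
        ]
    else:
        chunks = Parallel(n_jobs=batch_opts.workers)(
            delayed(_process_voxels)(
                j, data4d, scheme, L, lm_opts, mcmc_opts, batch_opts, shape, engine
            )
            for j in jobs
        )

    if keep_samples:
        n_keep = mcmc_opts.n_retained
        for name in param_names(L):
            result.samples[name] = np.zeros(shape + (n_keep,))

    for chunk in chunks:
        for ijk, post in chunk:
            means = posterior_means(post)
            result.mean_S0[ijk] = means["S0"]
            result.mean_d[ijk] = means["d"]
            for j in range(L):
                result.mean_f[(j,) + ijk] = means[f"f{j + 1}"]
                result.dyads[(j,) + ijk] = means[f"dyad{j + 1}"]
                result.dispersion[(j,) + ijk] = means[f"dispersion{j + 1}"]
            if keep_samples:
                for pi, name in enumerate(param_names(L)):
                    result.samples[name][ijk] = post.samples[:, pi]
    return result
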