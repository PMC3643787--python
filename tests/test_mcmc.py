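"""Sampler tests: priors, marginal likelihood, Metropolis kernel, streams."""

import math

import numpy as np
import pytest

from ballstick import (
    BallStickParams,
    generate_stream,
    log_marginal_likelihood,
    log_prior,
    metropolis_chain,
    predict_signal,
    run_mcmc,
    simulate_voxel,
)
from ballstick.mcmc import (
    ChainState,
    MCMCOptions,
    RandomStream,
    metropolis_update,
    project_into_support,
)


class TestLogPrior:
    def test_negative_fraction_outside_support(self):
        p = BallStickParams(S0=1, d=1e-3, f=[-0.1], theta=[1.0], phi=[0.0])
        assert log_prior(p) == -np.inf

    def test_simplex_violation_outside_support(self):
        p = BallStickParams(S0=1, d=1e-3, f=[0.6, 0.6], theta=[1, 1], phi=[0, 0])
        assert log_prior(p) == -np.inf

    def test_negative_d_outside_support(self):
        p = BallStickParams(S0=1, d=-1e-5, f=[0.5], theta=[1.0], phi=[0.0])
        assert log_prior(p) == -np.inf

    def test_equatorial_orientation_contributes_zero(self):
        p = BallStickParams(S0=1, d=1e-3, f=[0.5], theta=[np.pi / 2], phi=[0.3])
        assert log_prior(p) == pytest.approx(0.0, abs=1e-15)

    def test_two_stick_value_matches_direct_computation(self):
        p = BallStickParams(
            S0=1, d=1e-3, f=[0.3, 0.3], theta=[np.pi / 4, np.pi / 3], phi=[0, 1]
        )
        expected = math.log(math.sin(math.pi / 4)) + math.log(math.sin(math.pi / 3))
        assert log_prior(p) == pytest.approx(expected, rel=1e-12)


class TestLogMarginalLikelihood:
    def test_doubling_residuals_scaling_identity(self, scheme16, single_fibre_truth):
        pred = predict_signal(single_fibre_truth, scheme16)
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 2.0, pred.shape)
        K = scheme16.n_measurements
        l1 = log_marginal_likelihood(single_fibre_truth, pred + noise, scheme16)
        l2 = log_marginal_likelihood(single_fibre_truth, pred + 2 * noise, scheme16)
        assert l2 - l1 == pytest.approx(-(K / 2) * math.log(4.0), rel=1e-10)

    def test_perfect_fit_hits_floor(self, scheme16, single_fibre_truth):
        data = predict_signal(single_fibre_truth, scheme16)
        K = scheme16.n_measurements
        val = log_marginal_likelihood(single_fibre_truth, data, scheme16)
        assert val == pytest.approx(-(K / 2) * math.log(1e-12), rel=1e-12)

    def test_random_voxel_matches_recomputation(self, scheme16, single_fibre_truth):
        rng = np.random.default_rng(1)
        data = rng.uniform(10, 90, scheme16.n_measurements)
        ssr = float(np.sum((data - predict_signal(single_fibre_truth, scheme16)) ** 2))
        expected = -(scheme16.n_measurements / 2) * math.log(ssr)
        assert log_marginal_likelihood(
            single_fibre_truth, data, scheme16
        ) == pytest.approx(expected, rel=1e-12)

    def test_non_finite_data_rejected(self, scheme16, single_fibre_truth):
        data = np.full(scheme16.n_measurements, np.inf)
        with pytest.raises(ValueError):
            log_marginal_likelihood(single_fibre_truth, data, scheme16)


class TestMetropolisUpdate:
    def _state(self, x0):
        target = lambda x: -0.5 * float(x @ x)  # noqa: E731
        return ChainState(x=np.array(x0, float), log_post=target(np.array(x0))), target

    def test_zero_sd_always_accepts(self):
        state, target = self._state([0.3, -0.2])
        accepted = metropolis_update(state, 0, 1.7, 0.999, 0.0, target)
        assert accepted
        assert state.x[0] == 0.3  # numerically unchanged

    def test_out_of_support_always_rejected(self, scheme16, single_fibre_truth):
        from ballstick.mcmc import _log_posterior

        data = predict_signal(single_fibre_truth, scheme16)
        x = project_into_support(single_fibre_truth).to_vector()
        target = lambda v: _log_posterior(v, data, scheme16)  # noqa: E731
        state = ChainState(x=x.copy(), log_post=target(x))
        # parameter index 2 is f1; drive the proposal far negative
        accepted = metropolis_update(state, 2, -100.0, 1e-300, 0.05, target)
        assert not accepted
        assert state.x[2] == x[2]

    def test_acceptance_rate_matches_independent_scalar_chain(
        self, scheme16, single_fibre_truth
    ):
        """Seed-averaged acceptance vs a from-scratch pure-Python sampler."""
        data = simulate_voxel(single_fibre_truth, scheme16, snr=25, seed=5)
        sds = np.array([2.0, 5e-5, 0.03, 0.08, 0.08])
        opts = MCMCOptions(burnin=0, njumps=2000, sampleevery=10, adapt=False,
                           proposal_sds=sds)
        from ballstick import lm_fit

        init = project_into_support(lm_fit(data, scheme16, 1).params)
        K = scheme16.n_measurements

        def ref_chain(seed):
            # independent implementation: plain python/math only
            rng = np.random.default_rng(seed + 10_000)
            x = list(init.to_vector())

            def logpost(v):
                S0, d, f, th, ph = v
                if S0 < 0 or d < 0 or not (0 <= f <= 1) or math.sin(th) == 0:
                    return -math.inf
                xs = (
                    math.sin(th) * math.cos(ph),
                    math.sin(th) * math.sin(ph),
                    math.cos(th),
                )
                ssr = 0.0
                for i in range(K):
                    b = scheme16.bvals[i]
                    g = scheme16.bvecs[i]
                    dot = g[0] * xs[0] + g[1] * xs[1] + g[2] * xs[2]
                    s = S0 * (
                        (1 - f) * math.exp(-b * d)
                        + f * math.exp(-b * d * dot * dot)
                    )
                    ssr += (data[i] - s) ** 2
                return math.log(abs(math.sin(th))) - 0.5 * K * math.log(max(ssr, 1e-12))

            lp = logpost(x)
            acc = np.zeros(5)
            for _ in range(2000):
                for p in range(5):
                    old = x[p]
                    x[p] = old + sds[p] * rng.standard_normal()
                    lp_new = logpost(x)
                    if math.log(rng.random()) < lp_new - lp:
                        lp = lp_new
                        acc[p] += 1
                    else:
                        x[p] = old
            return acc / 2000

        ours = []
        for seed in range(4):
            stream = generate_stream(seed, opts, 5)
            post = run_mcmc(data, scheme16, init, opts, stream)
            ours.append(post.acceptance_fraction())
        ours = np.mean(ours, axis=0)
        ref = np.mean([ref_chain(s) for s in range(4)], axis=0)
        np.testing.assert_allclose(ours, ref, atol=0.02)


class TestStreams:
    def test_same_seed_identical_buffers(self):
        opts = MCMCOptions(burnin=10, njumps=20)
        a = generate_stream(42, opts, 5)
        b = generate_stream(42, opts, 5)
        np.testing.assert_array_equal(a.normals, b.normals)
        np.testing.assert_array_equal(a.uniforms, b.uniforms)

    def test_buffer_sizes_for_defaults(self):
        opts = MCMCOptions()  # burnin 3000, njumps 1250
        s = generate_stream(0, opts, 5)
        assert s.normals.shape == (4250, 5)
        assert s.normals.size == 21250
        assert s.uniforms.shape == (4250, 5)

    def test_normal_buffer_moments(self):
        opts = MCMCOptions(burnin=3000, njumps=1250)
        s = generate_stream(7, opts, 5)
        n = s.normals.size
        se_mean = 1.0 / math.sqrt(n)
        se_var = math.sqrt(2.0 / n)
        assert abs(s.normals.mean()) < 4 * se_mean
        assert abs(s.normals.var() - 1.0) < 4 * se_var


class TestRunMCMC:
    def test_zero_njumps_gives_empty_samples(self, scheme16, single_fibre_truth):
        data = simulate_voxel(single_fibre_truth, scheme16, snr=25, seed=1)
        opts = MCMCOptions(burnin=50, njumps=0)
        stream = generate_stream(0, opts, 5)
        post = run_mcmc(data, scheme16, single_fibre_truth, opts, stream)
        assert post.n_retained == 0
        assert post.final_state.shape == (5,)

    def test_retention_arithmetic(self, scheme16, single_fibre_truth):
        data = simulate_voxel(single_fibre_truth, scheme16, snr=25, seed=2)
        opts = MCMCOptions(burnin=100, njumps=330, sampleevery=40)
        stream = generate_stream(1, opts, 5)
        post = run_mcmc(data, scheme16, single_fibre_truth, opts, stream)
        assert post.n_retained == 330 // 40

    def test_bitwise_reproducible(self, scheme16, single_fibre_truth):
        data = simulate_voxel(single_fibre_truth, scheme16, snr=25, seed=3)
        opts = MCMCOptions(burnin=200, njumps=200, sampleevery=10)
        stream = generate_stream(9, opts, 5)
        a = run_mcmc(data, scheme16, single_fibre_truth, opts, stream)
        b = run_mcmc(data, scheme16, single_fibre_truth, opts, stream)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.final_state, b.final_state)

    def test_short_stream_rejected(self, scheme16, single_fibre_truth):
        data = simulate_voxel(single_fibre_truth, scheme16, snr=25, seed=4)
        opts = MCMCOptions(burnin=200, njumps=200)
        stream = generate_stream(0, MCMCOptions(burnin=10, njumps=10), 5)
        with pytest.raises(ValueError):
            run_mcmc(data, scheme16, single_fibre_truth, opts, stream)

    def test_samples_never_leave_prior_support(self, scheme16, single_fibre_truth):
        data = simulate_voxel(single_fibre_truth, scheme16, snr=10, seed=5)
        opts = MCMCOptions(burnin=500, njumps=500, sampleevery=5)
        stream = generate_stream(11, opts, 5)
        post = run_mcmc(data, scheme16, single_fibre_truth, opts, stream)
        for row in post.samples:
            BallStickParams.from_vector(row).validate()

    def test_posterior_concentrates_with_snr(self, scheme64, single_fibre_truth):
        """Median posterior spread of f shrinks as SNR grows through 10/30/100."""
        from ballstick import generate_stream, lm_fit, run_mcmc_batch

        opts = MCMCOptions(burnin=600, njumps=400, sampleevery=10)
        spreads = []
        for snr in (10, 30, 100):
            datas = np.stack(
                [
                    simulate_voxel(
                        single_fibre_truth, scheme64, snr=snr, seed=1000 * snr + i
                    )
                    for i in range(20)
                ]
            )
            fits = [lm_fit(d, scheme64, 1).params for d in datas]
            streams = [generate_stream(2000 + i, opts, 5) for i in range(20)]
            res = run_mcmc_batch(datas, scheme64, fits, opts, streams)
            spreads.append(np.median([r.samples[:, 2].std() for r in res]))
        assert spreads[0] > spreads[1] > spreads[2]


class TestTractableTarget:
    def test_standard_normal_moments(self):
        """Retained samples of a N(0,1) target have the right mean/variance."""
        opts = MCMCOptions(
            burnin=500, njumps=12000, sampleevery=2, proposal_sds=np.array([2.4]),
            adapt=False,
        )
        stream = generate_stream(123, opts, 1)
        post = metropolis_chain(
            lambda x: -0.5 * float(x @ x), np.zeros(1), opts, stream
        )
        xs = post.samples[:, 0]
        assert abs(xs.mean()) < 0.08
        assert abs(xs.var() - 1.0) < 0.15
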