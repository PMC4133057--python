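"""Water-filling allocation, whitening baseline, Wiener decoding."""

import numpy as np
import pytest
from scipy.optimize import minimize

from popcode.coding import (
    InfeasibleProblemError,
    assemble_encoder,
    encode_decode_samples,
    expected_mse_limit,
    random_orthogonal,
    recoverable_power,
    waterfill_allocation,
    whitening_encoder,
    wiener_decoder,
    wiener_decoder_dense,
)
from popcode.signal_model import BlurModel, GridGeometry, make_powerlaw_spectrum
from popcode.signal_model import CodingProblem, NoiseLevels


def oracle_mse(problem, n_subsets=True):
    """Independent oracle: minimize Σ λ−s·p/(p+σδ²) on the power simplex.

    For undercomplete problems every size-min(M,N) support is enumerated;
    within each support the smooth problem is solved with SLSQP.
    """
    from itertools import combinations

    lam = problem.signal.spectrum
    s = recoverable_power(
        lam, problem.blur.spectral_gains, problem.noise.sensory_variance
    )
    sd2 = problem.noise.neural_variance
    p_budget = problem.power_budget
    n = problem.n
    k = min(problem.m, n)

    def solve_support(idx):
        idx = list(idx)
        ss = s[idx]

        def f(p):
            return -np.sum(ss * p / (p + sd2))

        cons = [{"type": "eq", "fun": lambda p: p.sum() - p_budget}]
        x0 = np.full(len(idx), p_budget / len(idx))
        res = minimize(f, x0, bounds=[(0, p_budget)] * len(idx),
                       constraints=cons, method="SLSQP",
                       options={"maxiter": 200, "ftol": 1e-12})
        return float(lam.sum() + res.fun)

    best = np.inf
    for idx in combinations(range(n), k):
        best = min(best, solve_support(idx))
    return best


class TestRecoverablePower:
    @pytest.mark.parametrize(
        "lam,a,sn2,expected",
        [(1.0, 1.0, 0.0, 1.0), (1.0, 1.0, 1.0, 0.5), (1.0, 0.0, 0.7, 0.0),
         (1.0, 0.0, 0.0, 0.0)],
    )
    def test_closed_form(self, lam, a, sn2, expected):
        assert recoverable_power(lam, a, sn2) == pytest.approx(expected)

    def test_vectorized(self):
        out = recoverable_power(np.array([4.0, 1.0]), np.ones(2), 1.0)
        assert out == pytest.approx([16 / 5, 0.5])


class TestWaterfilling:
    def test_single_neuron_picks_strongest_component(self, diag_problem_factory):
        # brute force over both single-component choices: picking λ=4 gives
        # MSE 4·(1−1/2)+1 = 3 (60%); picking λ=1 gives 4+0.5 = 4.5
        problem = diag_problem_factory([4.0, 1.0], m=1, p=1.0)
        alloc = waterfill_allocation(problem)
        assert alloc.power == pytest.approx([1.0, 0.0])
        dec = wiener_decoder(
            assemble_encoder(alloc, problem.signal, np.eye(1), problem), problem
        )
        assert dec.expected_mse == pytest.approx(3.0, rel=1e-9)
        assert dec.percent_error == pytest.approx(60.0, rel=1e-9)

    def test_scalar_problem_spends_whole_budget(self, diag_problem_factory):
        problem = diag_problem_factory([2.0], m=1, p=3.7)
        alloc = waterfill_allocation(problem)
        assert alloc.power == pytest.approx([3.7])

    def test_symmetric_components_get_equal_power(self, diag_problem_factory):
        problem = diag_problem_factory([2.0, 2.0, 2.0], m=3, p=5.0)
        p = waterfill_allocation(problem).power
        assert p == pytest.approx([5 / 3] * 3)

    def test_budget_met_exactly(self, random_problem_factory):
        rng = np.random.default_rng(11)
        for _ in range(10):
            problem = random_problem_factory(rng)
            alloc = waterfill_allocation(problem)
            assert abs(alloc.total_power - problem.power_budget) <= 1e-9 * problem.power_budget
            assert alloc.n_active <= min(problem.m, problem.n)

    def test_matches_numerical_oracle(self, random_problem_factory):
        rng = np.random.default_rng(42)
        for _ in range(12):
            problem = random_problem_factory(rng, n=int(rng.integers(2, 7)))
            alloc = waterfill_allocation(problem)
            enc = assemble_encoder(
                alloc, problem.signal, np.eye(problem.m), problem
            )
            mse = wiener_decoder(enc, problem).expected_mse
            assert mse == pytest.approx(oracle_mse(problem), rel=1e-6)

    def test_infeasible_when_nothing_recoverable(self, diag_problem_factory):
        problem = diag_problem_factory([1.0, 1.0], a=[0.0, 0.0],
                                       sensory_variance=1.0, m=2, p=1.0)
        with pytest.raises(InfeasibleProblemError):
            waterfill_allocation(problem)

    def test_half_whitening_without_sensory_noise(self, diag_problem_factory):
        # representation variance p+σδ² ∝ √λ on the active set when σn²=0, a≡1
        lam = np.array([8.0, 4.0, 2.0, 1.0, 0.5])
        problem = diag_problem_factory(lam, m=5, p=40.0)
        alloc = waterfill_allocation(problem)
        act = alloc.active
        ratio = (alloc.power[act] + 1.0) / np.sqrt(lam[act])
        assert np.max(np.abs(ratio / ratio[0] - 1.0)) < 1e-6


class TestEncoderAssembly:
    def test_identity_case(self, diag_problem_factory):
        problem = diag_problem_factory([1.0, 1.0], m=2, p=2.0)
        alloc = waterfill_allocation(problem)
        enc = assemble_encoder(alloc, problem.signal, np.eye(2), problem)
        assert enc.W == pytest.approx(np.eye(2))

    def test_rejects_nonorthogonal_v(self, diag_problem_factory):
        problem = diag_problem_factory([1.0, 1.0], m=2, p=2.0)
        alloc = waterfill_allocation(problem)
        with pytest.raises(ValueError):
            assemble_encoder(alloc, problem.signal, np.array([[1.0, 0.1], [0.0, 1.0]]))

    def test_total_power_invariant_under_v(self, random_problem_factory):
        rng = np.random.default_rng(5)
        problem = random_problem_factory(rng, n=6, m=4)
        alloc = waterfill_allocation(problem)
        for _ in range(3):
            enc = assemble_encoder(
                alloc, problem.signal, random_orthogonal(4, rng), problem
            )
            total = enc.representation_variances().sum()
            assert total == pytest.approx(problem.power_budget, rel=1e-9)

    def test_mse_invariant_under_v(self, random_problem_factory):
        rng = np.random.default_rng(6)
        problem = random_problem_factory(rng, n=5, m=3)
        alloc = waterfill_allocation(problem)
        mses = []
        for _ in range(3):
            enc = assemble_encoder(
                alloc, problem.signal, random_orthogonal(3, rng), problem
            )
            # dense route: recompute the Wiener MSE from W itself
            mses.append(wiener_decoder_dense(enc.W, problem).expected_mse)
        assert np.ptp(mses) < 1e-9 * max(mses)


class TestWhitening:
    def test_scalar_closed_form(self, diag_problem_factory):
        problem = diag_problem_factory([4.0], m=1, p=1.0)
        enc = whitening_encoder(problem)
        assert abs(enc.W[0, 0]) == pytest.approx(0.5)

    def test_encoded_blurred_covariance_is_flat(self, random_problem_factory):
        rng = np.random.default_rng(9)
        for m in (2, 5):
            problem = random_problem_factory(rng, n=5, m=m)
            enc = whitening_encoder(problem)
            b = problem.blur.spectral_gains**2 * problem.signal.spectrum
            e = problem.signal.basis.full()
            u = enc.W @ e
            cov = (u * b) @ u.T
            c2 = cov[0, 0]
            assert np.max(np.abs(cov - c2 * np.eye(m))) < 1e-8 * c2

    def test_shape_independent_of_sensory_noise(self, diag_problem_factory):
        lam = [4.0, 2.0, 1.0]
        p_low = diag_problem_factory(lam, sensory_variance=0.01, m=3, p=5.0)
        p_high = diag_problem_factory(lam, sensory_variance=2.0, m=3, p=5.0)
        w_low, w_high = whitening_encoder(p_low).W, whitening_encoder(p_high).W
        scale = np.linalg.norm(w_high) / np.linalg.norm(w_low)
        assert w_high == pytest.approx(w_low * scale, rel=1e-9)

    def test_spends_power_budget(self, random_problem_factory):
        rng = np.random.default_rng(13)
        problem = random_problem_factory(rng, n=6, m=4)
        enc = whitening_encoder(problem)
        assert enc.representation_variances().sum() == pytest.approx(
            problem.power_budget, rel=1e-9
        )

    def test_undefined_for_overcomplete(self, diag_problem_factory):
        problem = diag_problem_factory([1.0, 1.0], m=3, p=1.0)
        with pytest.raises(ValueError):
            whitening_encoder(problem)


class TestWienerDecoder:
    def test_scalar_closed_form(self, diag_problem_factory):
        # λ=1, a=1, σn²=0, g=1 (p=1), σδ²=1 → G = 1·1/(1+1) = 1/2, MSE = 1/2
        problem = diag_problem_factory([1.0], m=1, p=1.0)
        alloc = waterfill_allocation(problem)
        enc = assemble_encoder(alloc, problem.signal, np.eye(1), problem)
        dec = wiener_decoder(enc, problem)
        assert dec.G == pytest.approx(np.array([[0.5]]))
        assert dec.expected_mse == pytest.approx(0.5)

    def test_vanishing_noise_perfect_reconstruction(self, diag_problem_factory):
        problem = diag_problem_factory(
            [2.0, 1.0], neural_variance=1e-12, m=2, p=1.0
        )
        alloc = waterfill_allocation(problem)
        enc = assemble_encoder(alloc, problem.signal, np.eye(2), problem)
        assert wiener_decoder(enc, problem).expected_mse < 1e-9

    def test_optimal_against_perturbed_readouts(self, random_problem_factory):
        rng = np.random.default_rng(21)
        problem = random_problem_factory(rng, n=4, m=3)
        alloc = waterfill_allocation(problem)
        enc = assemble_encoder(alloc, problem.signal, random_orthogonal(3, rng), problem)
        dec = wiener_decoder(enc, problem)

        def empirical_mse(g):
            # closed-form MSE of an arbitrary linear readout g of r
            e = problem.signal.basis.full()
            u = enc.W @ e
            d = problem.observed_spectrum()
            s_r = (u * d) @ u.T + problem.noise.neural_variance * np.eye(3)
            c_sr = (e * (problem.signal.spectrum * problem.blur.spectral_gains)) @ u.T
            return float(
                problem.signal.trace - 2 * np.trace(g.T @ c_sr) + np.trace(g @ s_r @ g.T)
            )

        base = empirical_mse(dec.G)
        assert base == pytest.approx(dec.expected_mse, rel=1e-8)
        for _ in range(10):
            g = dec.G + 0.05 * rng.standard_normal(dec.G.shape)
            assert empirical_mse(g) >= base - 1e-10


class TestMseLimit:
    def test_zero_when_undegraded(self, diag_problem_factory):
        problem = diag_problem_factory([3.0, 1.0], m=2, p=1.0)
        assert expected_mse_limit(problem) == pytest.approx(0.0)

    def test_closed_form(self, diag_problem_factory):
        problem = diag_problem_factory([4.0, 1.0], sensory_variance=1.0, m=2, p=1.0)
        assert expected_mse_limit(problem) == pytest.approx(1.3)

    def test_finite_m_mse_approaches_limit(self, diag_problem_factory):
        lam = np.array([4.0, 2.0, 1.0, 0.5])
        mses = []
        for m in (1, 2, 4, 16, 256, 4096):
            problem = diag_problem_factory(lam, sensory_variance=0.2, m=m, p=float(m))
            alloc = waterfill_allocation(problem)
            enc = assemble_encoder(
                alloc, problem.signal, np.eye(m), problem
            )
            mses.append(wiener_decoder(enc, problem).expected_mse)
        limit = expected_mse_limit(problem)
        assert np.all(np.diff(mses) <= 1e-12)
        assert np.all(np.array(mses) >= limit - 1e-12)
        assert mses[-1] == pytest.approx(limit, rel=0.02)


class TestDominance:
    def test_optimal_never_worse_than_whitening(self, random_problem_factory):
        rng = np.random.default_rng(33)
        for _ in range(15):
            problem = random_problem_factory(rng)
            alloc = waterfill_allocation(problem)
            enc = assemble_encoder(alloc, problem.signal, np.eye(problem.m), problem)
            opt = wiener_decoder(enc, problem).expected_mse
            wht = wiener_decoder(whitening_encoder(problem), problem).expected_mse
            assert opt <= wht + 1e-9 * wht


class TestEncodeDecodeSamples:
    def test_identity_pipeline_is_lossless(self, diag_problem_factory):
        problem = diag_problem_factory([1.0, 1.0], neural_variance=1e-30, m=2, p=2.0)
        alloc = waterfill_allocation(problem)
        enc = assemble_encoder(alloc, problem.signal, np.eye(2), problem)
        dec = wiener_decoder(enc, problem)
        s = np.array([[1.0, -0.5], [0.2, 0.3]])
        s_hat, _ = encode_decode_samples(enc, dec, s, problem, seed=0)
        assert s_hat == pytest.approx(s, abs=1e-6)

    def test_empirical_error_matches_closed_form(self):
        grid = GridGeometry(1, 16)
        cov = make_powerlaw_spectrum(grid, 2.0)
        blur = BlurModel.gaussian(cov, 0.5)
        problem = CodingProblem.from_snr(cov, blur, 16, 5.0, 10.0)
        alloc = waterfill_allocation(problem)
        rng = np.random.default_rng(2)
        enc = assemble_encoder(alloc, problem.signal, random_orthogonal(16, rng), problem)
        dec = wiener_decoder(enc, problem)
        from popcode.synth import TextureSpec, sample_textures

        s = sample_textures(TextureSpec(cov, seed=4), 10_000)
        _, emp = encode_decode_samples(enc, dec, s, problem, seed=5)
        # Monte-Carlo: 3σ band on the percent error estimate
        assert emp == pytest.approx(dec.percent_error, rel=0.1)

    def test_seeded_reproducibility(self, diag_problem_factory):
        problem = diag_problem_factory([2.0, 1.0], sensory_variance=0.5, m=2, p=2.0)
        alloc = waterfill_allocation(problem)
        enc = assemble_encoder(alloc, problem.signal, np.eye(2), problem)
        dec = wiener_decoder(enc, problem)
        s = np.random.default_rng(1).standard_normal((5, 2))
        a, _ = encode_decode_samples(enc, dec, s, problem, seed=9)
        b, _ = encode_decode_samples(enc, dec, s, problem, seed=9)
        assert np.array_equal(a, b)
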