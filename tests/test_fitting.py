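import numpy as np
import pytest

from boneeis import (
    CircuitParams,
    DegenerateDataError,
    FitOptions,
    GeneratorConfig,
    ImpedanceSpectrum,
    InsufficientDataError,
    InvalidArgumentError,
    circuit_impedance,
    class_mean_params,
    fit_spectrum,
    initial_guess,
    make_grid,
    r_squared,
    sample_spectrum,
)
from boneeis.fitting import _r2_concat, objective

GRID = make_grid()


def random_truth(rng):
    """Truths drawn where all four parameters are identifiable in-grid."""
    return CircuitParams(
        r_b=10 ** rng.uniform(3, 5),
        r_ct=10 ** rng.uniform(5.5, 7),
        q=10 ** rng.uniform(-7.5, -6),
        alpha=rng.uniform(0.55, 0.95),
    )


class TestInitialGuess:
    def test_bulk_resistance_from_high_frequency_plateau(self):
        cfg = GeneratorConfig(param_cv=0.0, noise_sd=0.0)
        rng = np.random.default_rng(0)
        params, spec = sample_spectrum(cfg, 100, rng)
        guess = initial_guess(spec)
        assert guess.r_b == pytest.approx(params.r_b, rel=0.05)

    def test_ideal_capacitor_alpha_guess(self):
        truth = CircuitParams(r_b=100.0, r_ct=1e7, q=1e-6, alpha=1.0)
        guess = initial_guess(circuit_impedance(truth, GRID))
        assert guess.alpha >= 0.9

    def test_too_few_points_rejected(self):
        s = circuit_impedance(
            CircuitParams(r_b=1e3, r_ct=1e6, q=1e-7, alpha=0.7), make_grid(1, 100, 3)
        )
        with pytest.raises(InsufficientDataError):
            initial_guess(s)


class TestObjective:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        truth = random_truth(rng)
        _, spec = sample_spectrum(
            GeneratorConfig(param_cv=0.0, noise_sd=0.02, seed=3), 60, rng
        )
        # independent scalar-loop evaluation of the weighted residual sum
        s_oracle = 0.0
        for i, f in enumerate(spec.grid.frequencies):
            w = 2 * np.pi * f
            zm = truth.r_b + 1.0 / (
                1.0 / truth.r_ct + truth.q * (1j * w) ** truth.alpha
            )
            z_obs = complex(spec.z_real[i], spec.z_imag[i])
            s_oracle += abs(zm - z_obs) ** 2 / abs(z_obs) ** 2
        assert objective(spec, truth, "modulus") == pytest.approx(s_oracle, rel=1e-12)

    def test_fit_reports_objective_at_its_own_params(self):
        rng = np.random.default_rng(8)
        _, spec = sample_spectrum(GeneratorConfig(noise_sd=0.02), 40, rng)
        res = fit_spectrum(spec, FitOptions(n_restarts=2, seed=0))
        assert res.objective == pytest.approx(
            objective(spec, res.params, "modulus"), rel=1e-9
        )


class TestNoiselessRecovery:
    def test_parameters_recovered_within_0p1_percent(self):
        rng = np.random.default_rng(2024)
        for i in range(20):
            truth = random_truth(rng)
            spec = circuit_impedance(truth, GRID)
            res = fit_spectrum(spec, FitOptions(seed=i))
            assert res.params.r_b == pytest.approx(truth.r_b, rel=1e-3)
            assert res.params.r_ct == pytest.approx(truth.r_ct, rel=1e-3)
            assert res.params.q == pytest.approx(truth.q, rel=1e-3)
            assert res.params.alpha == pytest.approx(truth.alpha, rel=1e-3)
            assert res.r_squared >= 0.9999
            assert res.converged


class TestNoisyRecovery:
    def test_median_bulk_resistance_error_under_2pct_noise(self):
        cfg = GeneratorConfig(param_cv=0.10, noise_sd=0.02)
        rng = np.random.default_rng(7)
        errors, r2s = [], []
        for i in range(50):
            truth, spec = sample_spectrum(cfg, [0, 20, 40, 60, 80, 100][i % 6], rng)
            res = fit_spectrum(spec, FitOptions(n_restarts=4, seed=i))
            errors.append(abs(res.params.r_b / truth.r_b - 1.0))
            r2s.append(res.r_squared)
        assert np.median(errors) <= 0.10
        assert np.median(r2s) >= 0.99


class TestRestartsAndWeighting:
    def test_objective_never_increases_with_more_restarts(self):
        rng = np.random.default_rng(21)
        _, spec = sample_spectrum(GeneratorConfig(noise_sd=0.05), 20, rng)
        objs = [
            fit_spectrum(spec, FitOptions(n_restarts=n, seed=77)).objective
            for n in (1, 2, 4, 8)
        ]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(objs, objs[1:]))

    def test_unit_weighting_agrees_with_grid_search_oracle(self):
        # alpha = 1 truth; coarse 20^3 log grid around the truth
        truth = CircuitParams(r_b=1e3, r_ct=1e5, q=1e-6, alpha=1.0)
        spec = circuit_impedance(truth, make_grid(1, 1e5, 40))
        res = fit_spectrum(spec, FitOptions(weighting="unit", seed=0))
        spacing = 0.05
        offsets = (np.arange(20) - 9) * spacing  # truth sits on a node
        grids = [
            np.log10(v) + offsets for v in (truth.r_b, truth.r_ct, truth.q)
        ]
        best, best_s = None, np.inf
        w = 2 * np.pi * spec.grid.frequencies
        for lrb in grids[0]:
            for lrct in grids[1]:
                for lq in grids[2]:
                    z = 10**lrb + 1.0 / (10**-lrct + 10**lq * 1j * w)
                    s = np.sum(np.abs(z - spec.z) ** 2)
                    if s < best_s:
                        best, best_s = (lrb, lrct, lq), s
        fitted = np.log10([res.params.r_b, res.params.r_ct, res.params.q])
        assert np.all(np.abs(fitted - np.array(best)) <= spacing + 1e-9)
        assert res.objective <= best_s + 1e-9
        assert res.params.alpha == pytest.approx(1.0, abs=1e-3)


class TestRSquared:
    def test_exact_model_gives_unity(self):
        p = CircuitParams(r_b=1e4, r_ct=1e6, q=1e-7, alpha=0.7)
        assert r_squared(circuit_impedance(p, GRID), p) == pytest.approx(1.0)

    def test_mean_predictor_gives_zero(self):
        rng = np.random.default_rng(5)
        z_obs = rng.normal(size=30) + 1j * rng.normal(size=30)
        z_mean = np.full(30, z_obs.real.mean()) + 1j * np.full(30, z_obs.imag.mean())
        assert _r2_concat(z_obs, z_mean) == pytest.approx(0.0, abs=1e-12)

    def test_fitted_noisy_spectrum_r2_high(self):
        rng = np.random.default_rng(31)
        _, spec = sample_spectrum(GeneratorConfig(noise_sd=0.02), 80, rng)
        res = fit_spectrum(spec, FitOptions(n_restarts=2, seed=1))
        assert res.r_squared >= 0.99

    def test_constant_spectrum_degenerate(self):
        g = make_grid(1, 100, 5)
        s = ImpedanceSpectrum(grid=g, z_real=np.ones(5), z_imag=np.zeros(5))
        with pytest.raises(DegenerateDataError):
            r_squared(s, CircuitParams(r_b=1, r_ct=1, q=1, alpha=1))


def test_non_finite_spectrum_rejected():
    g = make_grid(1, 100, 5)
    s = ImpedanceSpectrum(
        grid=g, z_real=[1, 2, np.nan, 4, 5], z_imag=np.zeros(5)
    )
    with pytest.raises(InvalidArgumentError):
        fit_spectrum(s)
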