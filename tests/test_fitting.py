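"""Parameter estimation: residual conventions, error metric, recovery."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from frorfot.fitting import (
    FitConfig,
    _jacobian,
    _residual_vector,
    fit_cohort,
    fit_spectrum,
    goodness_of_fit,
    residuals,
)
from frorfot.model import (
    FrequencyGrid,
    FrOrParameters,
    ImpedanceSpectrum,
    default_grid,
    evaluate_model,
)

from conftest import random_params


class TestResiduals:
    def test_zero_for_self_generated_spectrum(self, grid):
        p = FrOrParameters(FrL=0.15, alpha=0.6, FrC=0.04, beta=0.65)
        s = evaluate_model(p, grid)
        np.testing.assert_allclose(residuals(p, s), 0.0, atol=1e-14)

    def test_offset_on_resistance_only_hits_first_half(self, grid):
        p = FrOrParameters(FrL=0.15, alpha=0.6, FrC=0.04, beta=0.65)
        s = evaluate_model(p, grid)
        shifted = ImpedanceSpectrum("x", grid, s.zr + 0.7, s.zx)
        res = residuals(p, shifted)
        n = len(grid)
        np.testing.assert_allclose(res[:n], 0.7, rtol=1e-12)
        np.testing.assert_allclose(res[n:], 0.0, atol=1e-14)

    def test_matches_naive_elementwise_loop(self, rng, grid):
        p = random_params(rng)[0]
        zr = rng.normal(2, 1, len(grid))
        zx = rng.normal(0, 1, len(grid))
        s = ImpedanceSpectrum("x", grid, zr, zx)
        model = evaluate_model(p, grid)
        expected = [zr[i] - model.zr[i] for i in range(len(grid))] + [
            zx[i] - model.zx[i] for i in range(len(grid))
        ]
        np.testing.assert_allclose(residuals(p, s), expected, rtol=1e-14)


class TestGoodnessOfFit:
    def test_perfect_fit_is_zero(self, grid):
        p = FrOrParameters(FrL=0.15, alpha=0.6, FrC=0.04, beta=0.65)
        assert goodness_of_fit(p, evaluate_model(p, grid)) == (0.0, 0.0, 0.0)

    def test_constant_real_residual_arithmetic(self, grid):
        # residual 2 on every resistance point, 0 on reactance -> (4, 0, 2)
        p = FrOrParameters(FrL=0.15, alpha=0.6, FrC=0.04, beta=0.65)
        s = evaluate_model(p, grid)
        shifted = ImpedanceSpectrum("x", grid, s.zr + 2.0, s.zx)
        mse_r, mse_x, mse_t = goodness_of_fit(p, shifted)
        assert mse_r == pytest.approx(4.0, rel=1e-12)
        assert mse_x == pytest.approx(0.0, abs=1e-14)
        assert mse_t == pytest.approx(2.0, rel=1e-12)

    def test_matches_definition_on_random_residuals(self, rng, grid):
        p = random_params(rng)[0]
        model = evaluate_model(p, grid)
        er = rng.normal(0, 0.3, len(grid))
        ex = rng.normal(0, 0.3, len(grid))
        s = ImpedanceSpectrum("x", grid, model.zr + er, model.zx + ex)
        mse_r, mse_x, mse_t = goodness_of_fit(p, s)
        assert mse_r == pytest.approx(np.mean(er**2), rel=1e-10)
        assert mse_x == pytest.approx(np.mean(ex**2), rel=1e-10)
        assert mse_t == pytest.approx(np.sqrt(mse_r + mse_x), rel=1e-12)


def test_analytic_jacobian_matches_finite_differences(rng, grid):
    omega = grid.omega
    p = random_params(rng)[0].as_array()
    zr = np.zeros(len(grid))
    zx = np.zeros(len(grid))
    jac = _jacobian(p, omega, zr, zx)
    for row in range(2 * len(grid)):
        num = approx_fprime(
            p, lambda x, r=row: _residual_vector(x, omega, zr, zx)[r], 1e-7
        )
        np.testing.assert_allclose(jac[row], num, rtol=2e-4, atol=1e-6)


class TestFitSpectrum:
    def test_noise_free_identifiability(self, rng, grid):
        for p in random_params(rng, 10):
            fit = fit_spectrum(evaluate_model(p, grid))
            rel = np.abs(fit.params.as_array() - p.as_array()) / p.as_array()
            assert rel.max() < 1e-4
            assert fit.mse_t < 1e-8
            assert fit.converged

    def test_beta_truth_at_upper_bound(self, grid):
        p = FrOrParameters(FrL=0.2, alpha=0.8, FrC=0.05, beta=1.0)
        fit = fit_spectrum(evaluate_model(p, grid))
        assert 1.0 - 1e-3 <= fit.params.beta <= 1.0

    def test_invariant_to_frequency_row_order(self, rng, tmp_path):
        # same (frequency, zr, zx) triples written in shuffled row order
        # must fit to the identical parameters: spectra are canonicalised
        # to ascending frequency on read
        from frorfot.io import read_spectra, write_spectra

        p = FrOrParameters(FrL=0.15, alpha=0.6, FrC=0.04, beta=0.65)
        grid = default_grid()
        clean = evaluate_model(p, grid, subject_id="a")
        noisy = ImpedanceSpectrum(
            "a",
            grid,
            clean.zr + rng.normal(0, 0.15, len(grid)),
            clean.zx + rng.normal(0, 0.15, len(grid)),
        )
        write_spectra([noisy], tmp_path / "fwd.csv")
        lines = (tmp_path / "fwd.csv").read_text().splitlines()
        shuffled = [lines[0]] + list(rng.permutation(lines[1:]))
        (tmp_path / "shuf.csv").write_text("\n".join(shuffled) + "\n")
        fit_fwd = fit_spectrum(read_spectra(tmp_path / "fwd.csv")[0])
        fit_shuf = fit_spectrum(read_spectra(tmp_path / "shuf.csv")[0])
        assert fit_fwd.params == fit_shuf.params

    def test_mse_not_worse_than_any_start(self, rng, grid):
        from frorfot.fitting import _heuristic_start, _lattice_starts

        p = random_params(rng)[0]
        clean = evaluate_model(p, grid)
        s = ImpedanceSpectrum(
            "x",
            grid,
            clean.zr + rng.normal(0, 0.15, len(grid)),
            clean.zx + rng.normal(0, 0.15, len(grid)),
        )
        config = FitConfig()
        fit = fit_spectrum(s, config)
        starts = _lattice_starts(config) + [_heuristic_start(s, config)]
        for x0 in starts:
            mse_start = goodness_of_fit(FrOrParameters.from_array(x0), s)[2]
            assert fit.mse_t <= mse_start + 1e-12

    def test_too_few_frequencies_rejected(self):
        grid = FrequencyGrid(np.array([4.0, 8.0, 16.0]))
        p = FrOrParameters(FrL=0.15, alpha=0.6, FrC=0.04, beta=0.65)
        with pytest.raises(ValueError, match="frequencies"):
            fit_spectrum(evaluate_model(p, grid))

    def test_median_recovery_under_noise(self, rng, grid, light_fit_config):
        # symmetric zero-mean noise: median estimates stay near truth
        p = FrOrParameters(FrL=0.18, alpha=0.55, FrC=0.042, beta=0.58)
        clean = evaluate_model(p, grid)
        estimates = []
        for _ in range(200):
            s = ImpedanceSpectrum(
                "x",
                grid,
                clean.zr + rng.normal(0, 0.15, len(grid)),
                clean.zx + rng.normal(0, 0.15, len(grid)),
            )
            estimates.append(fit_spectrum(s, light_fit_config).params.as_array())
        med = np.median(estimates, axis=0)
        rel = np.abs(med - p.as_array()) / p.as_array()
        assert rel.max() < 0.05


class TestFitCohort:
    def test_noise_free_batch_matches_per_spectrum_fits(self, rng, grid):
        params = random_params(rng, 3)
        spectra = [
            evaluate_model(p, grid, subject_id=f"S{i}") for i, p in enumerate(params)
        ]
        table = fit_cohort(spectra)
        assert list(table["subject_id"]) == ["S0", "S1", "S2"]
        assert table["converged"].all()
        for i, p in enumerate(params):
            single = fit_spectrum(spectra[i])
            assert table.loc[i, "FrL"] == single.params.FrL
            assert table.loc[i, "beta"] == single.params.beta

    def test_corrupt_spectrum_flagged_not_fatal(self, rng, grid):
        p = random_params(rng)[0]
        good = evaluate_model(p, grid, subject_id="good")
        bad_zr = good.zr.copy()
        bad_zr[0] = np.nan
        bad = ImpedanceSpectrum("bad", grid, bad_zr, good.zx, strict=False)
        table = fit_cohort([good, bad])
        assert table.loc[0, "error"] == ""
        assert table.loc[1, "error"] != ""
        assert not table.loc[1, "converged"]
        assert np.isnan(table.loc[1, "FrL"])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            fit_cohort([])
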