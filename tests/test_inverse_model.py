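import numpy as np
import pytest

import enamelseason as es
from enamelseason.core import IsotopeSeries
from enamelseason.errors import (
    ConfigError,
    InsufficientDataError,
    InvalidInputError,
    SingularSystemError,
)
from enamelseason.inverse_model import (
    InversionConfig,
    choose_damping,
    invert_profile,
    invert_series,
    mc_error_bands,
    sensitivity_la,
)


def constant_series(value=14.0, n=10):
    centers = 1.0 + 2.0 * np.arange(n)
    return IsotopeSeries("const", centers, [np.array([value])] * n)


def truth_rmse(result, tooth):
    tv = np.interp(
        result.estimate.positions, tooth.truth.positions, tooth.truth.values
    )
    err = (result.estimate.values - tv)[result.interior]
    return float(np.sqrt(np.mean(err**2)))


class TestInvertProfile:
    @pytest.mark.parametrize("penalty", ["curvature", "roughness", "reference"])
    def test_constant_data_gives_constant_estimate(self, geometry, penalty):
        res = invert_profile(
            constant_series(), geometry, InversionConfig(damping=0.5, penalty=penalty)
        )
        np.testing.assert_allclose(res.estimate.values, 14.0, atol=1e-7)
        assert res.rms_misfit < 1e-7

    def test_damping_dominated_limit_returns_reference(self, geometry, make_tooth):
        tooth = make_tooth(0)
        res = invert_profile(
            tooth.series, geometry, InversionConfig(damping=1e6, penalty="reference")
        )
        ref = tooth.series.replicate_means().mean()
        assert np.max(np.abs(res.estimate.values - ref)) < 1e-3

    @pytest.mark.parametrize("start_month", [1.0, 4.0, 7.0, 10.0])
    def test_noise_free_round_trip(self, geometry, make_tooth, start_month):
        """Exact data re-invert to the true seasonal input on interior nodes."""
        tooth = make_tooth(
            0,
            meteoric_only=True,
            noise_sd=0.0,
            n_replicates=1,
            samples_min=12,
            samples_max=12,
            start_month_mean=start_month,
            start_month_sd=0.0,
        )
        res = invert_profile(tooth.series, geometry, InversionConfig(damping=1e-3))
        assert truth_rmse(res, tooth) < 0.3

    def test_too_few_samples(self, geometry):
        with pytest.raises(InsufficientDataError):
            invert_profile(constant_series(n=2), geometry)

    def test_zero_damping_underdetermined_raises(self, geometry):
        with pytest.raises(SingularSystemError):
            invert_profile(constant_series(), geometry, InversionConfig(damping=0.0))


class TestChooseDamping:
    def test_zero_budget_returns_grid_minimum(self, geometry, make_tooth, caplog):
        tooth = make_tooth(1)
        cfg = InversionConfig(sigma_meas=0.0, damping_grid=(0.01, 0.1, 1.0))
        with caplog.at_level("WARNING", logger="enamelseason.inverse_model"):
            eps = choose_damping(tooth.series, geometry, cfg)
        assert eps == 0.01
        assert any("misfit budget" in r.message for r in caplog.records)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            InversionConfig(damping_grid=())

    def test_misfit_within_noise_band_over_replicates(self, geometry, make_tooth):
        """Discrepancy-chosen damping lands the misfit near the injected noise."""
        misfits = []
        for seed in range(20):
            tooth = make_tooth(300 + seed, noise_sd=0.3, n_replicates=1)
            eps = choose_damping(tooth.series, geometry, InversionConfig(sigma_meas=0.3))
            res = invert_profile(tooth.series, geometry, InversionConfig(damping=eps))
            misfits.append(res.rms_misfit)
        assert all(0.15 <= m <= 0.45 for m in misfits)

    def test_misfit_non_decreasing_in_damping(self, geometry, make_tooth):
        tooth = make_tooth(2)
        misfits = [
            invert_profile(tooth.series, geometry, InversionConfig(damping=e)).rms_misfit
            for e in np.geomspace(1e-3, 10, 10)
        ]
        assert all(b >= a - 1e-10 for a, b in zip(misfits, misfits[1:]))

    def test_reference_regularization_path(self, geometry, make_tooth):
        """More damping pulls the estimate toward the reference, never away."""
        tooth = make_tooth(3)
        ref = tooth.series.replicate_means().mean()
        norms = []
        for e in np.geomspace(1e-3, 100, 10):
            res = invert_profile(
                tooth.series, geometry, InversionConfig(damping=e, penalty="reference")
            )
            norms.append(np.linalg.norm(res.estimate.values - ref))
        assert all(b <= a + 1e-8 for a, b in zip(norms, norms[1:]))


class TestMonteCarloBands:
    def test_identical_seeds_bitwise_identical(self, geometry, make_tooth):
        tooth = make_tooth(4)
        cfg = InversionConfig(damping=0.1, n_trials=50, seed=7)
        r1 = mc_error_bands(tooth.series, geometry, cfg)
        r2 = mc_error_bands(tooth.series, geometry, cfg)
        assert np.array_equal(r1.lower, r2.lower)
        assert np.array_equal(r1.upper, r2.upper)
        assert np.array_equal(r1.trials_summary, r2.trials_summary)

    def test_zero_sigma_bands_collapse(self, geometry, make_tooth):
        tooth = make_tooth(5)
        cfg = InversionConfig(damping=0.1, n_trials=50, seed=1, sigma_meas=0.0)
        res = mc_error_bands(tooth.series, geometry, cfg)
        np.testing.assert_allclose(res.lower, res.estimate.values, atol=1e-9)
        np.testing.assert_allclose(res.upper, res.estimate.values, atol=1e-9)

    def test_bands_bracket_estimate(self, geometry, make_tooth):
        tooth = make_tooth(6)
        res = mc_error_bands(
            tooth.series, geometry, InversionConfig(damping=0.1, n_trials=100, seed=2)
        )
        assert (res.lower <= res.estimate.values + 1e-9).all()
        assert (res.upper >= res.estimate.values - 1e-9).all()

    def test_zero_trials_rejected(self, geometry, make_tooth):
        tooth = make_tooth(7)
        with pytest.raises(ConfigError):
            mc_error_bands(tooth.series, geometry, InversionConfig(n_trials=0))


class TestSensitivityLa:
    def test_repeated_la_identical_rows(self, geometry, make_tooth):
        tooth = make_tooth(8)
        table = sensitivity_la(tooth.series, geometry, [7.0, 7.0, 7.0])
        assert len(table) == 3
        assert table["amplitude"].nunique() == 1
        assert table["rms_misfit"].nunique() == 1

    def test_matches_independent_reruns(self, geometry, make_tooth):
        """The sweep is just invert_profile re-run per apposition length."""
        tooth = make_tooth(9)
        cfg = InversionConfig(damping=0.05)
        table = sensitivity_la(tooth.series, geometry, [2.0, 7.0, 12.0], cfg)
        for la, amp in zip(table["la_mm"], table["amplitude"]):
            res = invert_profile(tooth.series, geometry.with_la(la), cfg)
            assert amp == pytest.approx(res.amplitude(), abs=1e-12)

    def test_non_positive_la_rejected(self, geometry, make_tooth):
        tooth = make_tooth(10)
        with pytest.raises(InvalidInputError):
            sensitivity_la(tooth.series, geometry, [7.0, -1.0])


class TestInvertSeries:
    def test_pipeline_recovers_known_input(self, geometry, make_tooth):
        """Typical noisy-tooth recovery error is a few tenths of a permil."""
        rmses = []
        for seed in range(5):
            tooth = make_tooth(seed)
            res = invert_series(
                tooth.series, geometry, InversionConfig(n_trials=50, seed=seed)
            )
            assert res.lower is not None
            rmses.append(truth_rmse(res, tooth))
        assert np.median(rmses) < 0.6
        assert max(rmses) < 1.5
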