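import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsmcell.errors import ConfigurationError
from dsmcell.fitting import (
    ActivationDataset,
    calibrate_cell,
    calibrate_model,
    fit_hill,
    gof_pass,
    rmse_s,
    synthetic_activation_curve,
)


class TestRmseS:
    def test_identical_series_give_zero(self):
        assert rmse_s([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_offset(self):
        assert rmse_s([0.0, 0.0], [1.0, 1.0], n_params=0) == 1.0

    def test_matches_independent_summation(self):
        rng = np.random.default_rng(7)
        ye, ys = rng.normal(size=40), rng.normal(size=40)
        total = 0.0
        for a, b in zip(ye, ys):  # explicit term-by-term accumulation
            total += (a - b) * (a - b)
        expected = math.sqrt(total / (40 - 3))
        assert abs(rmse_s(ye, ys, n_params=3) - expected) <= 1e-12

    @given(seed=st.integers(0, 1000))
    @settings(derandomize=True, max_examples=25)
    def test_invariant_under_common_permutation(self, seed):
        rng = np.random.default_rng(seed)
        ye, ys = rng.normal(size=15), rng.normal(size=15)
        perm = rng.permutation(15)
        assert rmse_s(ye[perm], ys[perm], 2) == pytest.approx(
            rmse_s(ye, ys, 2), rel=1e-12
        )

    def test_degrees_of_freedom_error(self):
        with pytest.raises(ConfigurationError, match="degrees of freedom"):
            rmse_s([1.0, 2.0], [1.0, 2.0], n_params=2)


class TestGofPass:
    def test_zero_error_passes(self):
        passed, thr = gof_pass(0.0, 1.0)
        assert passed and thr == 0.05

    def test_exactly_at_threshold_fails(self):
        passed, _ = gof_pass(5.0, 100.0)
        assert not passed  # strict inequality

    def test_threshold_is_five_percent_of_range(self):
        _, thr = gof_pass(1.0, 100.0)
        assert thr == 5.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ConfigurationError):
            gof_pass(0.1, 0.0)


class TestFitHill:
    def test_noiseless_recovery_within_one_percent(self):
        ds = synthetic_activation_curve(ca_half_mm=4e-4, hill_n=2.0, noise_sd=0.0)
        params, report = fit_hill(ds)
        assert params.ca_half_mm == pytest.approx(4e-4, rel=0.01)
        assert params.hill_n == pytest.approx(2.0, rel=0.01)
        assert report.s_statistic < 1e-6

    def test_noisy_fit_passes_range_rule(self):
        ds = synthetic_activation_curve(ca_half_mm=4e-4, hill_n=2.0,
                                        noise_sd=0.02, seed=3)
        _, report = fit_hill(ds)
        assert report.passed

    def test_tiny_dataset_rejected(self):
        with pytest.raises(ConfigurationError):
            ActivationDataset((1e-4,), (0.5,))

    def test_parameter_recovery_over_seeded_datasets(self):
        """Median relative parameter error < 5% at noise 0.02 across 20
        seeded datasets spanning Ca_half in [1e-4, 1e-2] mM, n in [1, 4]."""
        rng = np.random.default_rng(2024)
        errs = []
        for seed in range(20):
            cah = 10 ** rng.uniform(-4, -2)
            n = rng.uniform(1.0, 4.0)
            ds = synthetic_activation_curve(
                ca_half_mm=cah, hill_n=n, noise_sd=0.02,
                log10_min=math.log10(cah) - 2, log10_max=math.log10(cah) + 2,
                seed=seed,
            )
            params, _ = fit_hill(ds)
            errs.append(abs(params.ca_half_mm - cah) / cah)
            errs.append(abs(params.hill_n - n) / n)
        assert float(np.median(errs)) < 0.05


class TestCalibration:
    # toy: leak (gl, El) in parallel with an always-open K conductance
    # (gk, Ek); RMP = (gl*El + gk*Ek) / (gl + gk), with gk scaled by the
    # calibration factor.
    GL, EL, GK, EK = 0.27, 0.0, 2.0, -75.0

    def toy_rmp(self, factor):
        gk = self.GK * factor
        return (self.GL * self.EL + gk * self.EK) / (self.GL + gk)

    def evaluate(self, params):
        return {"rmp_mv": self.toy_rmp(params["kir"])}

    def test_recovers_analytic_factor(self):
        target = self.toy_rmp(1.17)
        report = calibrate_cell(
            self.evaluate,
            targets={"rmp_mv": target},
            parameters={"kir": 1.0},
            bounds={"kir": (0.7, 1.3)},
        )
        assert report.parameters["kir"] == pytest.approx(1.17, abs=1e-3)
        assert report.converged
        assert report.after["rmp_mv"] == pytest.approx(target, abs=1e-3)

    def test_already_met_targets_leave_parameters_unchanged(self):
        report = calibrate_cell(
            self.evaluate,
            targets={"rmp_mv": self.toy_rmp(1.0)},
            parameters={"kir": 1.0},
            bounds={"kir": (0.7, 1.3)},
        )
        assert report.parameters == {"kir": 1.0}

    def test_never_leaves_bounds(self):
        # unreachable target: best effort pinned at a bound, no exception
        report = calibrate_cell(
            self.evaluate,
            targets={"rmp_mv": -74.9},
            parameters={"kir": 1.0},
            bounds={"kir": (0.7, 1.3)},
        )
        assert 0.7 <= report.parameters["kir"] <= 1.3
        assert not report.converged

    def test_calibrated_default_model_is_at_its_target(self, model):
        """The shipped model already rests at -52 mV, so an RMP-only
        calibration is the identity."""
        calibrated, report = calibrate_model(
            model, {"rmp_mv": -52.0}, channels=("trpm4",), bound=0.3
        )
        assert report.parameters["trpm4"] == pytest.approx(1.0, abs=1e-6)
        assert report.converged
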