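"""Nonlinear least-squares estimation: exact recovery, invariances, diagnostics."""

import numpy as np
import pytest

import chachakit as ck
from chachakit.fitting import FitResult, IdentifiabilityError


def noiseless(cv=0.0, seed=0):
    return ck.NoiseModel(cv_or_sd=cv, seed=seed)


class TestSteadyStateFit:
    def test_noiseless_recovery_is_exact(self, demo_truth):
        data = ck.generate_grid_dataset(demo_truth, noise=noiseless())
        fit = ck.fit_steady_state_model(data)
        for name in ("G_max", "K_L", "K_A", "n_stoich"):
            assert fit.estimates[name] == pytest.approx(
                getattr(demo_truth, name), rel=1e-6
            )
        assert fit.r == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "free", [("G_max",), ("G_max", "K_L"), ("G_max", "K_L", "K_A")]
    )
    def test_noiseless_recovery_for_free_subsets(self, demo_truth, free):
        data = ck.generate_grid_dataset(demo_truth, noise=noiseless())
        fixed = {
            name: getattr(demo_truth, name)
            for name in ("G_max", "K_L", "K_A", "n_stoich")
            if name not in free
        }
        fit = ck.fit_steady_state_model(data, free=free, fixed=fixed)
        for name in free:
            assert fit.estimates[name] == pytest.approx(
                getattr(demo_truth, name), rel=1e-6
            )

    def test_record_order_invariance(self, demo_truth):
        data = ck.generate_grid_dataset(demo_truth, noise=noiseless(0.1, 3))
        shuffled = data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = ck.fit_steady_state_model(data)
        b = ck.fit_steady_state_model(shuffled)
        for name in a.estimates:
            assert a.estimates[name] == pytest.approx(b.estimates[name], rel=1e-7)

    def test_single_adaptor_level_is_not_identifiable(self, demo_truth):
        data = ck.generate_grid_dataset(
            demo_truth, adaptor_levels=[100.0, 100.0],
            ligand_doses=[1.0, 10.0, 100.0, 1000.0], noise=noiseless(),
        )
        with pytest.raises(IdentifiabilityError):
            ck.fit_steady_state_model(data)

    def test_stoichiometry_recovered_from_noisy_grid(self, demo_truth):
        """Median n over a handful of seeds lands near the generating 2.33."""
        ns = []
        for seed in (1, 2, 3, 4, 5):
            data = ck.generate_grid_dataset(demo_truth, noise=noiseless(0.1, seed))
            ns.append(ck.fit_steady_state_model(data).estimates["n_stoich"])
        assert np.median(ns) == pytest.approx(2.33, rel=0.10)

    def test_noisy_covariate_vs_true_covariate_option(self, demo_truth):
        data = ck.generate_grid_dataset(demo_truth, noise=noiseless(0.1, 6))
        fit_true = ck.fit_steady_state_model(data, use_true_adaptor=True)
        assert fit_true.converged
        # with the exact covariate the surface fit is at least as good
        fit_noisy = ck.fit_steady_state_model(data)
        assert fit_true.r >= fit_noisy.r - 0.02

    def test_loss_trace_is_monotone_nonincreasing(self, demo_truth):
        data = ck.generate_grid_dataset(demo_truth, noise=noiseless(0.1, 7))
        fit = ck.fit_steady_state_model(data)
        assert all(b <= a for a, b in zip(fit.loss_trace, fit.loss_trace[1:]))

    def test_estimator_median_bias_below_5pct(self, demo_truth):
        """Across 50 seeds at design scale, median n deviates <5% from truth."""
        ns = [
            ck.fit_steady_state_model(
                ck.generate_grid_dataset(demo_truth, noise=noiseless(0.1, seed))
            ).estimates["n_stoich"]
            for seed in range(101, 151)
        ]
        assert abs(np.median(ns) - 2.33) / 2.33 < 0.05

    def test_r_equals_pearson_of_observed_vs_fitted(self, demo_truth):
        data = ck.generate_grid_dataset(demo_truth, noise=noiseless(0.1, 8))
        fit = ck.fit_steady_state_model(data)
        obs = data["gfp"].to_numpy()
        assert fit.r == ck.pearson_r(obs, obs - fit.residuals)


class TestHillFit:
    truth = ck.DoseResponseParams(bottom=0.1, top=2.0, EC50=105.0, hill_slope=1.3)

    def test_noiseless_recovery_is_exact(self):
        data = ck.generate_dose_response(self.truth, noise=noiseless())
        fit = ck.fit_hill_dose_response(data)
        for name in ("bottom", "top", "EC50", "hill_slope"):
            assert fit.estimates[name] == pytest.approx(
                getattr(self.truth, name), rel=1e-6, abs=1e-9
            )

    def test_ec50_reported_with_standard_error(self):
        data = ck.generate_dose_response(self.truth, noise=noiseless(0.1, 2))
        fit = ck.fit_hill_dose_response(data)
        se = fit.standard_errors["EC50"]
        assert se is not None and np.isfinite(se) and se > 0

    def test_too_few_distinct_doses_rejected(self):
        data = ck.generate_dose_response(self.truth, doses=[1.0, 10.0, 100.0],
                                         noise=noiseless())
        with pytest.raises(IdentifiabilityError):
            ck.fit_hill_dose_response(data)


class TestDoxHillFit:
    truth = ck.DoxInductionParams(kappa1=100.0, kappa2=10.0, K_D=100.0, n_hill=1.0)
    levels = np.geomspace(1.0, 10000.0, 8)

    def test_noiseless_recovery_of_unit_cooperativity(self):
        data = ck.generate_dox_induction(self.truth, self.levels, noise=noiseless())
        fit = ck.fit_dox_hill(data)
        assert fit.estimates["n_hill"] == pytest.approx(1.0, rel=1e-6)
        assert fit.estimates["K_D"] == pytest.approx(100.0, rel=1e-5)

    def test_dose_rescaling_leaves_cooperativity_unchanged(self):
        data = ck.generate_dox_induction(self.truth, self.levels, noise=noiseless())
        rescaled = data.copy()
        rescaled["dox_level"] = 2 * rescaled["dox_level"]
        a = ck.fit_dox_hill(data).estimates["n_hill"]
        b = ck.fit_dox_hill(rescaled).estimates["n_hill"]
        assert a == pytest.approx(b, rel=1e-5)

    def test_noisy_fits_rarely_exceed_1p2(self):
        hits = 0
        for seed in range(1, 9):
            data = ck.generate_dox_induction(
                self.truth, self.levels, noise=noiseless(0.1, seed)
            )
            hits += ck.fit_dox_hill(data).estimates["n_hill"] <= 1.2
        assert hits >= 7


class TestPearsonR:
    def test_perfect_and_anti_correlation(self):
        x = [1.0, 2.0, 5.0]
        assert ck.pearson_r(x, x) == pytest.approx(1.0)
        assert ck.pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # obs {1,2,3}, fit {1,2,4}: r = 9/sqrt(84) by direct formula
        assert ck.pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(9 / np.sqrt(84))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ck.pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            ck.pearson_r([1, 2], [1, 2])


def test_fit_result_serializes_to_json(tmp_path, demo_truth):
    data = ck.generate_grid_dataset(demo_truth, noise=noiseless(0.1, 1))
    fit = ck.fit_steady_state_model(data)
    path = tmp_path / "fit.json"
    fit.save(path)
    import json

    loaded = json.loads(path.read_text())
    assert loaded["estimates"]["n_stoich"] == fit.estimates["n_stoich"]
    assert loaded["converged"] is True
    assert isinstance(fit, FitResult)
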