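"""Functional-response fitting: likelihood correctness against brute-force
oracles, closed forms, enumeration bookkeeping and parameter recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats

from patchfr.frfit import (
    FitError,
    FunctionalResponseModel,
    ScalingEstimate,
    ScalingSpec,
    enumerate_form_specs,
    enumerate_scaling_specs,
    fit_max_feeding,
    fit_scaling_model,
    hill_test,
    nb_loglik,
    predict_N0_h,
    real_fr,
    select_model,
)
from patchfr.synth import default_design, make_synthetic_feeding_table

INTERCEPT_ONLY = ScalingSpec(
    include_a_n0=False, include_b_n0=False, include_gamma_n0=False,
    include_a_h=False, include_b_h=False, include_gamma_h=False,
)
WINNING = ScalingSpec(
    include_gamma_n0=False, include_a_h=False, include_b_h=False,
    include_gamma_h=False,
)


class TestRealFR:
    def test_half_saturation_definition(self):
        for h in (0.5, 1.0, 1.284, 3.0):
            assert real_fr(100.0, fmax=6.7, N0=100.0, h=h) == pytest.approx(3.35)

    def test_saturates_to_fmax(self):
        assert real_fr(1e12, fmax=6.7, N0=100.0, h=1.0) == pytest.approx(6.7, rel=1e-6)

    def test_direct_evaluation(self):
        expected = 6.7 * 50**1.284 / (100**1.284 + 50**1.284)
        assert real_fr(50.0, 6.7, 100.0, 1.284) == pytest.approx(expected, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        for bad in [dict(N0=-1.0), dict(h=0.0), dict(fmax=0.0)]:
            kwargs = dict(N=1.0, fmax=6.7, N0=100.0, h=1.0)
            kwargs.update(bad)
            with pytest.raises(ValueError):
                real_fr(**kwargs)


class TestMaxFeedingGLM:
    def test_constant_sample_exact(self):
        ln_f, se, p = fit_max_feeding([7] * 12)
        assert ln_f == pytest.approx(np.log(7.0), rel=1e-10)
        assert se == pytest.approx(1.0 / np.sqrt(84.0), rel=1e-4)

    def test_closed_form_intercept_and_se(self):
        ln_f, se, _ = fit_max_feeding([5, 6, 7, 8])
        assert ln_f == pytest.approx(np.log(6.5), rel=1e-10)
        assert se == pytest.approx(1.0 / np.sqrt(26.0), rel=1e-4)

    def test_all_zero_degenerate(self):
        with pytest.raises(FitError):
            fit_max_feeding([0, 0, 0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_max_feeding([])


class TestNBLoglik:
    def _tiny(self):
        return pd.DataFrame(
            {
                "area_m2": [0.04, 0.04, 1.44, 1.44, 36.0, 36.0, 0.16, 0.64],
                "refuge_fraction": [0.05, 0.75, 0.25, 0.45, 0.35, 0.15, 0.55, 0.65],
                "density_per_m2": [25.0, 50.0, 10.0, 400.0, 3.0, 900.0, 77.0, 120.0],
                "eaten": [0, 1, 0, 5, 0, 7, 2, 3],
            }
        )

    def test_matches_bruteforce_pmf_oracle(self):
        """Row-by-row scipy.stats.nbinom log-pmf summed by hand equals the
        vectorised likelihood to 1e-10."""
        data = self._tiny()
        spec = ScalingSpec()
        params = np.array([4.2, -0.1, 1.5, 0.05, 0.22, 0.03, 0.08, 0.01, 1.2])
        ll = nb_loglik(params, spec, data, ln_fmax_fixed=1.9)

        est = ScalingEstimate(spec, tuple(params[:-1]) + (0.0,), 1.9)
        # oracle: explicit per-row mean and scipy pmf in the (n, p) form
        total = 0.0
        k = np.exp(params[-1])
        for _, row in data.iterrows():
            n0, h = est.predict_n0_h(row.area_m2, row.refuge_fraction)
            mu = np.exp(1.9) * row.density_per_m2**h / (n0**h + row.density_per_m2**h)
            total += scipy.stats.nbinom.logpmf(row.eaten, k, k / (k + mu))
        assert ll == pytest.approx(total, abs=1e-10)

    def test_additivity_under_duplication(self):
        data = self._tiny()
        doubled = pd.concat([data, data], ignore_index=True)
        params = np.array([4.0, 0.0, 1.0, 0.0, 0.2, 0.0, 0.0, 0.0, 0.8])
        spec = ScalingSpec()
        assert nb_loglik(params, spec, doubled, 1.9) == pytest.approx(
            2.0 * nb_loglik(params, spec, data, 1.9), rel=1e-12
        )

    def test_poisson_limit_at_large_k(self):
        data = self._tiny()
        params = np.array([4.0, 0.2, 30.0])  # intercepts + ln k
        ll = nb_loglik(params, INTERCEPT_ONLY, data, 1.9)
        n0, h = np.exp(4.0), np.exp(0.2)
        mu = np.exp(1.9) * data.density_per_m2**h / (n0**h + data.density_per_m2**h)
        poisson = scipy.stats.poisson.logpmf(data.eaten, mu).sum()
        assert ll == pytest.approx(poisson, rel=1e-6)

    def test_nonfinite_params_give_nonfinite_loglik(self):
        data = self._tiny()
        params = np.array([np.nan, 0.2, 1.0])
        assert not np.isfinite(nb_loglik(params, INTERCEPT_ONLY, data, 1.9))


class TestPredict:
    def test_intercept_only_is_constant(self):
        est = ScalingEstimate(INTERCEPT_ONLY, (4.0, 0.25, 1.0), 1.9)
        for a, r in itertools.product((0.04, 1.0, 100.0), (0.05, 0.75)):
            n0, h = est.predict_n0_h(a, r)
            assert n0 == pytest.approx(np.exp(4.0))
            assert h == pytest.approx(np.exp(0.25))

    def test_plugin_evaluation_of_reported_scaling(self):
        # ln N0 = 4.577 + 1.777 R at unit patch size, h = exp(0.25)
        est = ScalingEstimate(WINNING, (4.577, -0.007, 1.777, 0.25, 1.0), 1.902)
        n0, h = predict_N0_h(1.0, 0.35, est)
        assert n0 == pytest.approx(np.exp(4.577 + 1.777 * 0.35), rel=1e-12)
        assert h == pytest.approx(np.exp(0.25), rel=1e-12)

    def test_separable_without_interaction(self):
        est = ScalingEstimate(WINNING, (4.5, -0.1, 1.5, 0.2, 1.0), 1.9)
        n0_a1_r1, _ = est.predict_n0_h(0.04, 0.05)
        n0_a2_r1, _ = est.predict_n0_h(2.56, 0.05)
        n0_a1_r2, _ = est.predict_n0_h(0.04, 0.75)
        n0_a2_r2, _ = est.predict_n0_h(2.56, 0.75)
        assert n0_a2_r2 / n0_a1_r2 == pytest.approx(n0_a2_r1 / n0_a1_r1, rel=1e-10)

    def test_log_refuge_form_rejects_zero(self):
        spec = ScalingSpec(include_a_h=True, include_b_h=True, include_gamma_h=False)
        est = ScalingEstimate(
            spec,
            (4.5, -0.1, 1.5, 0.1, 0.2, 0.0, 0.1, 1.0)[: spec.n_params - 1] + (1.0,),
            1.9,
        )
        with pytest.raises(ValueError):
            est.predict_n0_h(1.0, 0.0)


class TestFitting:
    def test_recovery_on_known_scaling(self, synth_table):
        truth, table = synth_table
        res = fit_scaling_model(table, WINNING, 1.9)
        for name, true_val in truth.items():
            est = res[name]
            se = res.se(name)
            assert abs(est - true_val) < 3 * se, (name, est, true_val, se)
        # slopes also land within 10% of the generating values
        assert res["b_N0"] == pytest.approx(truth["b_N0"], rel=0.10)

    def test_matches_gridsearch_oracle_on_flat_data(self, flat_table):
        """On homogeneous data the intercept-only MLE must beat or match an
        independent coarse-to-fine grid+simplex search of the same
        likelihood surface written directly against scipy.stats."""
        truth, table = flat_table
        res = fit_scaling_model(table, INTERCEPT_ONLY, 1.9)

        y = table["eaten"].to_numpy()
        N = table["density_per_m2"].to_numpy()

        def negll(p):
            n0, h, k = np.exp(p)
            mu = np.exp(1.9) * N**h / (n0**h + N**h)
            ll = scipy.stats.nbinom.logpmf(y, k, k / (k + mu)).sum()
            return -ll if np.isfinite(ll) else 1e12

        grid_best = min(
            (
                scipy.optimize.minimize(negll, [ln_n0, ln_h, 1.0], method="Nelder-Mead")
                for ln_n0 in np.linspace(2.0, 6.0, 5)
                for ln_h in (-0.3, 0.0, 0.4)
            ),
            key=lambda r: r.fun,
        )
        assert res.llf >= -grid_best.fun - 1e-4
        assert res["ln_C_N0"] == pytest.approx(grid_best.x[0], abs=0.02)
        assert res["ln_C_h"] == pytest.approx(grid_best.x[1], abs=0.02)

    def test_bic_definition(self, flat_table):
        _, table = flat_table
        res = fit_scaling_model(table, INTERCEPT_ONLY, 1.9)
        assert res.bic == pytest.approx(
            -2.0 * res.llf + res.params.size * np.log(len(table))
        )

    def test_density_unit_covariance(self, synth_table):
        """Refitting with densities per cm^2 shifts only the N0 intercept
        (by h * ln 1e4 on the ln-mean scale it compensates exactly);
        slopes and the Hill exponent are unit-invariant."""
        _, table = synth_table
        res_m = fit_scaling_model(table, WINNING, 1.9)
        rescaled = table.copy()
        rescaled["density_per_m2"] = rescaled["density_per_m2"] / 1e4
        res_cm = fit_scaling_model(rescaled, WINNING, 1.9)
        assert res_cm["b_N0"] == pytest.approx(res_m["b_N0"], abs=0.02)
        assert res_cm["a_N0"] == pytest.approx(res_m["a_N0"], abs=0.02)
        assert res_cm["ln_C_h"] == pytest.approx(res_m["ln_C_h"], abs=0.02)
        assert res_cm["ln_C_N0"] == pytest.approx(
            res_m["ln_C_N0"] - np.log(1e4), abs=0.05
        )

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            FunctionalResponseModel(pd.DataFrame({"eaten": [1]}), 1.9)


class TestHillTest:
    def test_null_hill_exponent(self):
        res = _result_with(ln_C_h=0.0, se=0.1)
        h, p = hill_test(res)
        assert h == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_reported_type_iii_case(self):
        res = _result_with(ln_C_h=0.25, se=0.011)
        h, p = hill_test(res)
        assert h == pytest.approx(1.284, abs=5e-4)
        assert p < 1e-3

    def test_z_is_estimate_over_se(self):
        res = _result_with(ln_C_h=0.2, se=0.05)
        i = res.param_names.index("ln_C_h")
        assert res.zvalues[i] == pytest.approx(4.0)


def _result_with(ln_C_h, se):
    """Assemble a fitted-result shell around fixed estimates for the Wald
    arithmetic tests."""
    from patchfr.frfit import FunctionalResponseResult

    table = pd.DataFrame(
        {
            "area_m2": [1.0, 2.0],
            "refuge_fraction": [0.1, 0.2],
            "density_per_m2": [10.0, 20.0],
            "eaten": [1, 2],
        }
    )
    model = FunctionalResponseModel(table, 1.9, INTERCEPT_ONLY)
    params = np.array([4.0, ln_C_h, 1.0])
    bse = np.array([0.1, se, 0.2])
    return FunctionalResponseResult(
        model=model, params=params, bse=bse, llf=-10.0, cov_params=np.diag(bse**2)
    )


class TestEnumeration:
    def test_scaling_selection_has_25_candidates(self):
        specs = enumerate_scaling_specs()
        assert len(specs) == 25
        assert len(set(specs)) == 25

    def test_form_screen_has_16_candidates(self):
        specs = enumerate_form_specs()
        assert len(specs) == 16
        assert len(set(specs)) == 16

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError):
            ScalingSpec(include_a_n0=False, include_gamma_n0=True)
        for spec in enumerate_scaling_specs():
            if spec.include_gamma_n0:
                assert spec.include_a_n0 and spec.include_b_n0

    def test_all_forms_coincide_at_zero_slopes(self):
        """With every slope at zero the 16 form candidates describe the same
        constant-(N0, h) model, so their likelihoods agree exactly."""
        table = default_design(reps=1)
        table["eaten"] = 1
        vals = set()
        for spec in enumerate_form_specs():
            params = np.zeros(spec.n_params)
            params[0] = 4.0
            params[-1] = 1.0
            vals.add(round(nb_loglik(params, spec, table, 1.9), 9))
        assert len(vals) == 1


@pytest.fixture(scope="module")
def selected(synth_table):
    _, table = synth_table
    return select_model(table, 1.9)


class TestSelection:
    def test_null_data_prefers_intercept_only(self):
        """Without any injected habitat effect the BIC choice should be the
        intercept-only structure in a clear majority of replicates."""
        wins = 0
        for seed in range(3):
            table = make_synthetic_feeding_table(
                {"ln_C_N0": 4.0, "ln_C_h": 0.2},
                default_design(reps=2, exponents=tuple(range(0, 14, 2))),
                k=6.0,
                seed=seed,
            )
            best, tab = select_model(table, 1.9)
            assert len(tab) == 25
            n_slopes = sum(
                getattr(best.spec, f)
                for f in (
                    "include_a_n0", "include_b_n0", "include_gamma_n0",
                    "include_a_h", "include_b_h", "include_gamma_h",
                )
            )
            wins += n_slopes == 0
        assert wins >= 2

    def test_recovers_injected_structure(self, selected):
        best, tab = selected
        assert best.spec.include_b_n0
        assert not best.spec.include_gamma_n0
        assert tab["bic"].min() == pytest.approx(best.bic)

    def test_bic_rank_bookkeeping(self, selected):
        _, tab = selected
        ordered = tab.sort_values("rank")
        assert ordered["bic"].is_monotonic_increasing
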