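"""Degradation kinetics, humidity-corrected Arrhenius regression, shelf life."""

import numpy as np
import pytest

from filadose.stability import (
    ArrheniusModel,
    GAS_CONSTANT_KCAL,
    StabilityCondition,
    degradation_curve,
    fit_arrhenius,
    fit_degradation,
    invert_degradation,
    predict_shelf_life,
)
from filadose.simulate import GeneratorSpec, gen_stability_study


def _condition(days, degraded, temp=343.15, rh=50.0):
    return StabilityCondition(
        temperature=temp,
        rh=rh,
        observations=list(zip(days, degraded)),
        convention="percent_degraded",
    )


class TestDegradationFits:
    def test_exact_zero_order_selected_and_recovered(self):
        t = [14.0, 28.0, 48.0]
        fits = fit_degradation(_condition(t, [0.2 * d for d in t]))
        assert fits[0].model == "zero"
        assert fits[0].k == pytest.approx(0.2, rel=1e-12)
        assert fits[0].r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_avrami_selected_and_recovered(self):
        k = 2e-5
        t = np.array([14.0, 28.0, 48.0, 60.0])
        d = 100.0 * (1.0 - np.exp(-k * t**2))
        fits = fit_degradation(_condition(t, d))
        assert fits[0].model == "avrami"
        assert fits[0].k == pytest.approx(k, rel=0.01)

    @pytest.mark.parametrize("model, k", [("first", 0.004), ("diffusion", 0.9)])
    def test_noise_free_generating_model_always_selected(self, model, k):
        t = np.array([7.0, 14.0, 28.0, 48.0])
        d = degradation_curve(model, k, t)
        fits = fit_degradation(_condition(t, d))
        assert fits[0].model == model
        assert fits[0].k == pytest.approx(k, rel=1e-6)

    def test_nonlinear_fit_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(11)
        t = np.array([7.0, 14.0, 28.0, 48.0])
        d = degradation_curve("avrami", 1.5e-5, t) * rng.lognormal(0, 0.02, t.size)
        fit = next(
            f for f in fit_degradation(_condition(t, d)) if f.model == "avrami"
        )
        grid = np.linspace(0.5e-5, 3e-5, 4000)
        sse = [
            float(np.sum((d - degradation_curve("avrami", k, t)) ** 2)) for k in grid
        ]
        assert fit.k == pytest.approx(grid[int(np.argmin(sse))], abs=grid[1] - grid[0])

    def test_flat_data_yields_zero_rate(self):
        fits = fit_degradation(_condition([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))
        assert all(f.k == 0.0 and f.flat for f in fits)

    def test_remaining_convention_converted_at_ingest(self):
        t = [14.0, 28.0, 48.0]
        cond = StabilityCondition(
            temperature=343.15,
            rh=50.0,
            observations=[(d, 100.0 - 0.2 * d) for d in t],
            convention="percent_remaining",
        )
        assert fit_degradation(cond)[0].k == pytest.approx(0.2, rel=1e-12)

    def test_condition_validation(self):
        with pytest.raises(ValueError):
            StabilityCondition(temperature=200.0, rh=50.0)
        with pytest.raises(ValueError):
            StabilityCondition(temperature=300.0, rh=120.0)
        with pytest.raises(ValueError):
            fit_degradation(_condition([1.0, 2.0], [0.1, 0.2]))


class TestArrhenius:
    def test_noise_free_parameter_recovery_to_a_tenth_percent(self):
        study = gen_stability_study(32.5, 23.38, 0.008, "zero")
        pairs = [(c, fit_degradation(c, models=("zero",))[0].k) for c in study]
        af = fit_arrhenius(pairs)
        assert af.ea == pytest.approx(23.38, rel=1e-3)
        assert af.b == pytest.approx(0.008, rel=1e-3)
        assert af.ln_a == pytest.approx(32.5, rel=1e-3)
        assert af.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_humidity_insensitive_limit(self):
        study = gen_stability_study(32.5, 23.38, 0.0, "zero")
        pairs = [(c, fit_degradation(c, models=("zero",))[0].k) for c in study]
        af = fit_arrhenius(pairs)
        assert abs(af.b) < 1e-8

    def test_equal_temperature_rh_contrast_is_pure_humidity_term(self):
        study = gen_stability_study(32.5, 23.38, 0.008, "zero")
        af = fit_arrhenius(
            [(c, fit_degradation(c, models=("zero",))[0].k) for c in study]
        )
        delta = af.ln_k(353.15, 75.0) - af.ln_k(353.15, 10.0)
        assert delta == pytest.approx(af.b * 65.0, rel=1e-12)

    def test_fixed_rh_log_rate_linear_in_inverse_temperature(self):
        af = fit_arrhenius(
            [
                (c, fit_degradation(c, models=("zero",))[0].k)
                for c in gen_stability_study(30.0, 22.0, 0.005, "zero")
            ]
        )
        temps = np.array([310.0, 320.0, 330.0, 340.0])
        lnk = np.array([af.ln_k(t, 50.0) for t in temps])
        resid = lnk - np.polyval(np.polyfit(1 / temps, lnk, 1), 1 / temps)
        assert np.max(np.abs(resid)) < 1e-10

    def test_rank_deficient_designs_rejected(self):
        base = gen_stability_study(32.5, 23.38, 0.008, "zero").conditions
        same_t = [c for c in base if c.temperature == 353.15]
        with pytest.raises(ValueError, match="temperature"):
            ArrheniusModel([(c, 0.1) for c in same_t + same_t[:1]])
        same_rh = [(base[2], 0.1), (base[5], 0.2), (base[2], 0.1)]
        with pytest.raises(ValueError, match="RH"):
            ArrheniusModel(same_rh)
        with pytest.raises(ValueError, match="> 0"):
            ArrheniusModel([(base[0], 0.1), (base[2], -1.0), (base[4], 0.2)])


class TestShelfLife:
    def test_zero_order_closed_form(self):
        days = invert_degradation("zero", 0.00913, 10.0)
        assert days == pytest.approx(10.0 / 0.00913, rel=1e-12)
        assert days == pytest.approx(1095, abs=1)
        assert days / 365.25 == pytest.approx(3.0, abs=0.01)

    def test_halving_rate_doubles_zero_order_shelf_life(self):
        assert invert_degradation("zero", 0.005, 10.0) == pytest.approx(
            2 * invert_degradation("zero", 0.01, 10.0), rel=1e-12
        )

    @pytest.mark.parametrize("model", ["zero", "first", "second", "diffusion", "avrami"])
    def test_inversion_round_trips_through_forward_curve(self, model):
        k = {"zero": 0.01, "first": 1e-3, "second": 2e-6, "diffusion": 0.3, "avrami": 1e-6}[
            model
        ]
        days = invert_degradation(model, k, 10.0)
        assert degradation_curve(model, k, np.array([days]))[0] == pytest.approx(
            10.0, abs=1e-9
        )

    def test_full_prediction_pipeline_consistency(self):
        study = gen_stability_study(32.5, 23.38, 0.008, "zero")
        af = fit_arrhenius(
            [(c, fit_degradation(c, models=("zero",))[0].k) for c in study]
        )
        pred = predict_shelf_life(af, "zero")
        k_expected = np.exp(32.5 - 23.38 / (GAS_CONSTANT_KCAL * 298.15) + 0.008 * 60)
        assert pred.k_extrapolated == pytest.approx(k_expected, rel=1e-6)
        assert pred.shelf_life_days == pytest.approx(10.0 / k_expected, rel=1e-6)
        forward = degradation_curve("zero", pred.k_extrapolated, np.array([pred.shelf_life_days]))
        assert forward[0] == pytest.approx(pred.specification_limit, abs=1e-9)

    def test_unreachable_limit_rejected(self):
        with pytest.raises(ValueError):
            invert_degradation("first", 0.01, 10.0, d_inf=5.0)
        with pytest.raises(ValueError):
            invert_degradation("zero", 0.0, 10.0)


class TestEndToEndRecovery:
    def test_noisy_shelf_life_recovery_within_fifteen_percent(self):
        """Full pipeline at 2% noise recovers the analytic shelf life."""
        ln_a, ea, b = 32.5, 23.38, 0.008
        k_true = np.exp(ln_a - ea / (GAS_CONSTANT_KCAL * 298.15) + b * 60)
        truth_days = 10.0 / k_true
        errors = []
        for seed in range(100):
            study = gen_stability_study(
                ln_a, ea, b, "zero",
                spec=GeneratorSpec(
                    seed=seed, noise_model="multiplicative_lognormal", noise_scale=0.02
                ),
            )
            af = fit_arrhenius(
                [(c, fit_degradation(c, models=("zero",))[0].k) for c in study]
            )
            pred = predict_shelf_life(af, "zero")
            errors.append(abs(pred.shelf_life_days - truth_days) / truth_days)
        assert np.median(errors) < 0.15
        assert np.mean(np.array(errors) < 0.15) >= 0.9
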