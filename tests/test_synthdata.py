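"""Generator sanity: the simulated survey must honour its own model."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from predselect.synthdata import (
    OtolithGrowthParams,
    PopulationParams,
    RetentionCurve,
    SelectionSpec,
    generate_otoliths,
    generate_population,
    sample_consumed,
    sample_net_catch,
)
from predselect.otolith import Calibration, reconstruct_sl_from_radius


class TestGeneratePopulation:
    def test_row_count_matches_request(self):
        pop = generate_population(PopulationParams(n_individuals=10_000, seed=0))
        assert len(pop) == 10_000

    def test_zero_sigma_puts_every_fish_on_the_mean_line(self):
        p = PopulationParams(n_individuals=200, sigma=0.0, seed=1)
        pop = generate_population(p)
        np.testing.assert_allclose(pop["sl"], p.beta0 + p.beta1 * pop["age"])

    def test_mean_sl_at_age_matches_the_stated_normal_model(self):
        # Monte-Carlo against SL | age=30 ~ N(10 + 1*30, 2^2)
        p = PopulationParams(
            n_individuals=50_000, beta0=10.0, beta1=1.0, sigma=2.0,
            age_range=(20, 40), seed=2,
        )
        pop = generate_population(p)
        at30 = pop.loc[pop["age"] == 30, "sl"]
        assert abs(at30.mean() - 40.0) < 3 * 2.0 / np.sqrt(len(at30))

    def test_fixed_seed_reproduces_byte_identical_tables(self):
        p = PopulationParams(n_individuals=500, seed=7)
        pd.testing.assert_frame_equal(generate_population(p), generate_population(p))

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_individuals": 0},
            {"beta1": -0.1},
            {"sigma": -1.0},
            {"age_range": (30, 30)},
            {"beta0": float("nan")},
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            PopulationParams(**bad)


class TestNetCatch:
    def test_full_retention_returns_a_plain_subsample(self, population):
        ret = RetentionCurve(l50=-100.0, delta=0.5)  # retention ~ 1 everywhere
        net = sample_net_catch(population, ret, len(population), seed=3)
        assert len(net) == len(population)

    def test_net_above_all_fish_warns_and_returns_short(self, population):
        ret = RetentionCurve(l50=population["sl"].max() + 50, delta=0.5)
        with pytest.warns(UserWarning, match="retained only"):
            net = sample_net_catch(population, ret, 10, seed=4)
        assert len(net) < 10

    def test_increasing_retention_biases_netted_mean_upward(self, population):
        ret = RetentionCurve(l50=population["sl"].mean(), delta=3.0)
        net = sample_net_catch(population, ret, 500, seed=5)
        # brute-force expectation over the generated population
        w = ret(population["sl"].to_numpy())
        expected = np.average(population["sl"], weights=w)
        assert net["sl"].mean() > population["sl"].mean()
        assert abs(net["sl"].mean() - expected) < 0.5


class TestConsumed:
    def test_random_selection_preserves_the_age_sl_slope(self, population, pop_params):
        cons = sample_consumed(
            population, SelectionSpec("random"), 500, seed=6, params=pop_params
        )
        slope = np.polyfit(cons["age"], cons["sl"], 1)[0]
        se = pop_params.sigma / (cons["age"].std() * np.sqrt(len(cons)))
        assert abs(slope - pop_params.beta1) < 4 * se

    def test_size_selection_shifts_consumed_mean_below_population(
        self, population, pop_params
    ):
        spec = SelectionSpec("size", l50_or_e50=30.0, width=2.0)
        cons = sample_consumed(population, spec, 300, seed=7, params=pop_params)
        # weighted-mean oracle on the population table
        from predselect.synthdata import selection_weights

        w = selection_weights(population, spec, pop_params)
        oracle = np.average(population["sl"], weights=w)
        assert cons["sl"].mean() < population["sl"].mean()
        assert abs(cons["sl"].mean() - oracle) < 1.5

    def test_growth_selection_skews_residuals_but_not_ages(
        self, population, pop_params
    ):
        spec = SelectionSpec("growth", l50_or_e50=-2.0, width=2.0)
        cons = sample_consumed(population, spec, 200, seed=8, params=pop_params)
        resid = cons["sl"] - (pop_params.beta0 + pop_params.beta1 * cons["age"])
        assert resid.mean() < 0
        assert ks_2samp(cons["age"], population["age"]).pvalue > 0.01

    def test_random_consumed_mean_converges_over_replicates(
        self, population, pop_params
    ):
        n = 50
        means = [
            sample_consumed(
                population, SelectionSpec("random"), n, seed=100 + r, params=pop_params
            )["sl"].mean()
            for r in range(100)
        ]
        delta = abs(np.mean(means) - population["sl"].mean())
        assert delta < 3 * pop_params.sigma / np.sqrt(n)

    def test_all_zero_weight_request_fails(self, population, pop_params):
        spec = SelectionSpec("size", l50_or_e50=-1e6, width=0.1)  # weights underflow
        with pytest.raises(ValueError, match="zero"):
            sample_consumed(population, spec, 5, seed=9, params=pop_params)


class TestOtoliths:
    def test_increment_count_is_age_minus_hatch_age(self):
        fish = pd.DataFrame({"id": ["f1"], "age": [30], "sl": [30.0]})
        oto = generate_otoliths(fish, OtolithGrowthParams(), noise_sd=0.0)
        assert (oto["n_increments"] == 28).all()

    def test_noise_free_left_right_identical(self, population):
        fish = population.head(5)
        oto = generate_otoliths(fish, OtolithGrowthParams(), noise_sd=0.0)
        left = oto[oto["side"] == "left"].set_index("fish_id")["radius_um"]
        right = oto[oto["side"] == "right"].set_index("fish_id")["radius_um"]
        pd.testing.assert_series_equal(left, right, check_names=False)

    def test_noise_free_radius_round_trips_to_true_sl(self, population):
        fish = population.head(10)
        oto = generate_otoliths(fish, OtolithGrowthParams(), noise_sd=0.0)
        calib = Calibration()
        for _, row in oto[oto["side"] == "left"].iterrows():
            truth = float(fish.loc[fish["id"] == row["fish_id"], "sl"].iloc[0])
            assert reconstruct_sl_from_radius(row["radius_um"], calib) == pytest.approx(
                truth, abs=1e-9
            )
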