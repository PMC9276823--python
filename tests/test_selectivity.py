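"""Population inference, selection likelihoods, AIC and bootstrap LRT."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from predselect.selectivity import (
    PopulationModel,
    SelectionFit,
    aic,
    bootstrap_lrt,
    compare_models,
    fit_population,
    fit_selection,
    loglik,
)
from predselect.synthdata import (
    PopulationParams,
    RetentionCurve,
    SelectionSpec,
    generate_population,
    sample_consumed,
    sample_net_catch,
)


def _uniform_pop_model(beta0=1.2, beta1=0.9, sigma=3.0, ages=(20, 70)):
    grid = np.arange(*ages)
    return PopulationModel(
        beta0=beta0, beta1=beta1, sigma=sigma,
        ages=grid, age_weights=np.full(grid.size, 1.0 / grid.size),
    )


class TestFitPopulation:
    def test_unit_retention_reduces_to_ols(self, netted):
        flat = RetentionCurve(l50=-200.0, delta=1.0)  # retention == 1 in float
        weighted = fit_population(netted, flat)
        ols = sm.OLS(netted["sl"], sm.add_constant(netted["age"].astype(float))).fit()
        assert weighted.beta0 == pytest.approx(ols.params.iloc[0], abs=1e-9)
        assert weighted.beta1 == pytest.approx(ols.params.iloc[1], abs=1e-9)

    def test_singular_design_rejected(self):
        df = pd.DataFrame({"age": [30] * 6, "sl": [25.0, 26, 27, 24, 25, 26]})
        with pytest.raises(ValueError, match="singular"):
            fit_population(df)

    def test_slope_recovered_within_2se_in_most_replicates(self):
        # parameter-recovery simulation; HC3 sandwich SE as the yardstick
        # (the weights correct sampling bias, not residual variance)
        ret = RetentionCurve(l50=25.0, delta=3.0)
        hits = 0
        reps = 200
        for r in range(reps):
            p = PopulationParams(n_individuals=3000, seed=1000 + r)
            pop = generate_population(p)
            net = sample_net_catch(pop, ret, 60, seed=2000 + r)
            ages = net["age"].to_numpy(dtype=float)
            w = 1.0 / np.maximum(ret(net["sl"].to_numpy()), 1e-12)
            se = (
                sm.WLS(net["sl"].to_numpy(), sm.add_constant(ages), weights=w)
                .fit(cov_type="HC3")
                .bse[1]
            )
            m = fit_population(net, ret)
            hits += abs(m.beta1 - p.beta1) < 2 * se
        assert hits / reps >= 0.90

    def test_retention_weighting_reduces_slope_bias(self):
        # strong net bias: weighting on should track the true slope better
        ret = RetentionCurve(l50=38.0, delta=4.0)
        err_w, err_u = [], []
        for r in range(200):
            p = PopulationParams(n_individuals=3000, seed=5000 + r)
            pop = generate_population(p)
            net = sample_net_catch(pop, ret, 80, seed=6000 + r)
            err_w.append(abs(fit_population(net, ret).beta1 - p.beta1))
            err_u.append(abs(fit_population(net, None).beta1 - p.beta1))
        assert np.mean(err_w) < np.mean(err_u)


class TestLoglik:
    def test_random_model_matches_closed_form(self, pop_model, consumed_random):
        got = loglik("random", None, pop_model, consumed_random)
        pop = pop_model.covering(consumed_random["age"].to_numpy())
        expected = float(
            np.sum(
                pop.log_f0(consumed_random["age"].to_numpy())
                + norm.logpdf(
                    consumed_random["sl"],
                    pop.mean_sl(consumed_random["age"]),
                    pop.sigma,
                )
            )
        )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_flat_selection_recovers_random_loglik(self, pop_model, consumed_random):
        base = loglik("random", None, pop_model, consumed_random)
        for kind in ("size", "growth"):
            wide = loglik(kind, (0.0, 1e9), pop_model, consumed_random)
            assert wide == pytest.approx(base, abs=1e-6)

    def test_growth_loglik_invariant_under_age_shift(self):
        # residuals unchanged, uniform age support => identical likelihood
        pop = _uniform_pop_model()
        rng = np.random.default_rng(4)
        ages = rng.integers(25, 45, 30)
        sl = pop.mean_sl(ages) + rng.normal(-1.5, 2.0, 30)
        base = pd.DataFrame({"age": ages, "sl": sl})
        shift = pd.DataFrame({"age": ages + 10, "sl": sl + pop.beta1 * 10})
        th = (-2.0, 2.0)
        assert loglik("growth", th, pop, base) == pytest.approx(
            loglik("growth", th, pop, shift), abs=1e-9
        )

    def test_size_loglik_matches_grid_oracle(self, pop_model, consumed_random):
        # independent 2000-point trapezoid normaliser on a 20-record sample
        sample = consumed_random.head(20)
        theta = (35.0, 2.5)
        got = loglik("size", theta, pop_model, sample)
        pop = pop_model.covering(sample["age"].to_numpy())
        grid = np.linspace(
            pop.mean_sl(pop.ages.min()) - 10 * pop.sigma,
            pop.mean_sl(pop.ages.max()) + 10 * pop.sigma,
            2000,
        )
        w_grid = expit(-(grid - theta[0]) / theta[1])
        z = sum(
            pa * np.trapezoid(norm.pdf(grid, pop.mean_sl(a), pop.sigma) * w_grid, grid)
            for a, pa in zip(pop.ages, pop.age_weights)
        )
        expected = float(
            np.sum(
                pop.log_f0(sample["age"].to_numpy())
                + norm.logpdf(sample["sl"], pop.mean_sl(sample["age"]), pop.sigma)
                + np.log(expit(-(sample["sl"] - theta[0]) / theta[1]))
            )
            - len(sample) * np.log(z)
        )
        assert got == pytest.approx(expected, abs=1e-5)


class TestFitSelection:
    def test_aic_identity_and_nesting(self, pop_model, consumed_growth):
        fits = {
            k: fit_selection(k, pop_model, consumed_growth)
            for k in ("random", "size", "growth")
        }
        for f in fits.values():
            assert f.aic == pytest.approx(aic(f.loglik, f.k), abs=1e-6)
        for k in ("size", "growth"):
            assert fits[k].loglik >= fits["random"].loglik - 1e-6

    @staticmethod
    def _induced_shift(half, width, sigma):
        """Mean residual of consumed fish implied by a growth-selection
        theta: the identifiable functional of the weakly identified
        (half, width) pair. Independent 400-node quadrature."""
        x, gw = np.polynomial.legendre.leggauss(400)
        eps = x * 8 * sigma
        gw = gw * 8 * sigma
        phi = norm.pdf(eps, 0.0, sigma)
        wv = expit(-(eps - half) / width)
        return float(((eps * phi * wv) @ gw) / ((phi * wv) @ gw))

    def test_growth_selection_strength_recovered(self):
        # half-point -2 mm, width 2 mm, n=100: the induced residual shift
        # of the fitted model lands within +/-50% of the truth (half and
        # width individually sit on a likelihood ridge and trade off)
        ret = RetentionCurve()
        spec = SelectionSpec("growth", l50_or_e50=-2.0, width=2.0)
        hits = 0
        reps = 60
        for r in range(reps):
            p = PopulationParams(n_individuals=3000, seed=300 + r)
            pop = generate_population(p)
            net = sample_net_catch(pop, ret, 60, seed=400 + r)
            cons = sample_consumed(pop, spec, 100, seed=500 + r, params=p)
            pm = fit_population(net, ret)
            fit = fit_selection("growth", pm, cons)
            truth = self._induced_shift(-2.0, 2.0, p.sigma)
            got = self._induced_shift(*fit.theta, pm.sigma)
            hits += got * truth > 0 and 0.5 * abs(truth) <= abs(got) <= 1.5 * abs(truth)
        assert hits / reps >= 0.80

    def test_too_few_consumed_rejected(self, pop_model, consumed_random):
        with pytest.raises(ValueError, match="at least 5"):
            fit_selection("size", pop_model, consumed_random.head(3))


class TestBootstrap:
    def test_p_reproducible_and_in_unit_interval(self, pop_model, consumed_random):
        p1 = bootstrap_lrt(pop_model, consumed_random, "growth", B=100, seed=9)
        p2 = bootstrap_lrt(pop_model, consumed_random, "growth", B=100, seed=9)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_null_collapse_gives_p_of_one(self, pop_model, consumed_random):
        base = loglik("random", None, pop_model, consumed_random)
        degenerate = SelectionFit("growth", (0.0, 1e7), base, 2, aic(base, 2))
        p = bootstrap_lrt(
            pop_model, consumed_random, "growth", B=100, seed=10, alt_fit=degenerate
        )
        assert p == 1.0

    def test_strong_size_selection_detected(self):
        p0 = PopulationParams(n_individuals=3000, seed=21)
        pop = generate_population(p0)
        net = sample_net_catch(pop, RetentionCurve(), 60, seed=22)
        cons = sample_consumed(
            pop, SelectionSpec("size", l50_or_e50=30.0, width=2.0), 50,
            seed=23, params=p0,
        )
        pm = fit_population(net, RetentionCurve())
        assert bootstrap_lrt(pm, cons, "size", B=199, seed=24) < 0.05


class TestCompareModels:
    def test_selected_attains_min_aic_and_boot_skippable(
        self, pop_model, consumed_growth
    ):
        cm = compare_models(pop_model, consumed_growth, boot_B=0)
        aics = {k: f.aic for k, f in cm.fits.items()}
        assert aics[cm.selected] == min(aics.values())
        assert all(f.boot_p is None for f in cm.fits.values())

    def test_bootstrap_p_attached_to_selective_fits(self, pop_model, consumed_growth):
        cm = compare_models(pop_model, consumed_growth, boot_B=100, seed=3)
        assert cm.fits["random"].boot_p is None
        for k in ("size", "growth"):
            assert 0 < cm.fits[k].boot_p <= 1

    def test_growth_simulation_prefers_growth_model(self, pop_model, consumed_growth):
        cm = compare_models(pop_model, consumed_growth, boot_B=0)
        assert cm.selected == "growth"
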