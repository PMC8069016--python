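"""Estimation tests: marginal-likelihood oracle, degenerate exact fits,
Wald arithmetic, IWRES diagnostics, VPC behaviour and AIC model ranking."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import kstest

from rutinpk.design import StudyDesign, StudyGroup, simulate_study
from rutinpk.estimation import (
    EstimationError,
    PopPKModel,
    PopPKResults,
    SAEMSettings,
    compare_models,
    compute_iwres,
    fit_population,
    vpc,
    wald_test,
)
from rutinpk.population import (
    CovariateEffect,
    PopulationModel,
    RandomEffectsSpec,
    ResidualErrorModel,
)
from rutinpk.reference import iv_reference_model
from rutinpk.structural import ROUTE_IV

FAST = SAEMSettings(n_burn=60, n_smooth=60, n_is=300, fim_n_is=150)


def tiny_iv_design(n=2, groups=(1,)):
    base = StudyDesign(groups=tuple(
        StudyGroup(g, f"g{g}", ROUTE_IV, "RU", 1.45, 1.45, "RU", n=n)
        for g in groups))
    return base


def one_compartment_spec(omega_v=0.2, omega_k=0.15, a=30.0, b=0.1):
    """Effectively one-compartment IV model (negligible distribution)."""
    return PopulationModel(
        structural="iv",
        fixed_effects={"V": 0.07, "k": 1.2, "k12": 1e-6, "k21": 1.0},
        covariate_axis="source", levels=("RU",), effects=(),
        random_effects=RandomEffectsSpec(sd={"V": omega_v, "k": omega_k}),
        error=ResidualErrorModel(a=a, b=b),
    )


class TestMarginalLikelihoodOracle:
    def test_importance_sampling_matches_gauss_hermite(self):
        """2-subject, effectively one-compartment toy: the importance-sampled
        marginal log-likelihood must agree with adaptive-free 2-D
        Gauss-Hermite quadrature over the random effects."""
        spec = one_compartment_spec()
        design = tiny_iv_design(n=2)
        data = simulate_study(design, spec, None, seed=5)
        # keep only 3 observations per subject
        data = [replace(s, times=s.times[1:4], dv=s.dv[1:4], blq=s.blq[1:4])
                for s in data]
        model = PopPKModel(data, spec, fix=())

        got = model.loglik(seed=3, n_is=20_000)

        # independent oracle: tensor-product Gauss-Hermite over (eta_V, eta_k)
        from numpy.polynomial.hermite_e import hermegauss
        nodes, weights = hermegauss(41)
        expected = 0.0
        sd_v, sd_k = 0.2, 0.15
        for s in data:
            t, y = s.quantifiable
            total = 0.0
            for zi, wi in zip(nodes, weights):
                for zj, wj in zip(nodes, weights):
                    V = 1 / (1 + np.exp(-(np.log(0.07 / 0.93) + sd_v * zi)))
                    k = 1.2 * np.exp(sd_k * zj)
                    k12, k21 = 1e-6, 1.0
                    ssum = k12 + k21 + k
                    disc = math.sqrt(ssum ** 2 - 4 * k21 * k)
                    al, be = (ssum + disc) / 2, (ssum - disc) / 2
                    c0 = 1000 * 1.45 / V
                    A = c0 * (al - k21) / (al - be)
                    B = c0 * (k21 - be) / (al - be)
                    f = A * np.exp(-al * t) + B * np.exp(-be * t)
                    sd = 30.0 + 0.1 * f
                    ll = np.sum(-0.5 * np.log(2 * np.pi * sd ** 2)
                                - 0.5 * ((y - f) / sd) ** 2)
                    total += wi * wj * math.exp(ll)
            expected += math.log(total / (2 * math.pi))
        assert got == pytest.approx(expected, abs=0.05)


class TestDegenerateFits:
    def test_single_free_parameter_recovered_exactly(self):
        """Noise-free data with no random effects: maximising the exact
        observation likelihood must recover the generating value."""
        truth = one_compartment_spec(omega_v=0.0, omega_k=0.0, a=0.0, b=0.0)
        data = simulate_study(tiny_iv_design(n=3), truth, None, seed=1)
        start = replace(truth,
                        fixed_effects={**truth.fixed_effects, "k": 0.6},
                        random_effects=RandomEffectsSpec(sd={}),
                        error=ResidualErrorModel(a=1.0, b=0.01))
        res = fit_population(
            data, start, seed=2, settings=FAST,
            fix=("V_pop", "k12_pop", "k21_pop", "a", "b"))
        assert res.estimates["k_pop"] == pytest.approx(1.2, rel=1e-3)

    def test_preflight_rejects_unidentifiable_beta(self, iv_study, iv_model):
        ru_only = [s for s in iv_study if s.level == "RU"]
        with pytest.raises(EstimationError, match="GEXT"):
            PopPKModel(ru_only, iv_model)

    def test_preflight_rejects_single_subject(self, iv_study, iv_model):
        with pytest.raises(EstimationError):
            PopPKModel(iv_study[:1], iv_model)


class TestWald:
    def _stub(self, estimates, se):
        return PopPKResults(model=None, theta=np.zeros(1), estimates=estimates,
                            se=se, loglik=0.0, aic=0.0, n_free=1,
                            eta_modes=np.zeros((1, 0)),
                            history=np.zeros((1, 1)), seed=0,
                            settings=SAEMSettings(), final_step_norm=0.0)

    def test_significant_extract_effect_on_volume(self):
        fit = self._stub({"beta_V_GEXT": 0.478}, {"beta_V_GEXT": 0.128})
        z, p = wald_test(fit, "beta_V_GEXT")
        assert z == pytest.approx(3.73, abs=0.01)
        assert p < 0.05

    def test_non_significant_lag_shift(self):
        fit = self._stub({"beta_Tlag2_D500": 0.149}, {"beta_Tlag2_D500": 0.0936})
        z, p = wald_test(fit, "beta_Tlag2_D500")
        assert z == pytest.approx(1.59, abs=0.01)
        assert p > 0.05

    def test_zero_estimate_gives_p_one(self):
        fit = self._stub({"b0": 0.0}, {"b0": 0.5})
        _, p = wald_test(fit, "b0")
        assert p == pytest.approx(1.0)

    def test_zero_se_rejected(self):
        fit = self._stub({"b0": 1.0}, {"b0": 0.0})
        with pytest.raises(EstimationError):
            wald_test(fit, "b0")


class TestIWRES:
    def test_zero_noise_residuals_are_zero(self):
        truth = one_compartment_spec(omega_v=0.0, omega_k=0.0, a=0.0, b=0.0)
        data = simulate_study(tiny_iv_design(n=3), truth, None, seed=4)
        model = PopPKModel(data, truth)
        fit = PopPKResults(model=model, theta=model.engine.layout.theta0,
                           estimates={}, se={}, loglik=0.0, aic=0.0, n_free=0,
                           eta_modes=np.zeros((len(data), model.engine.q)),
                           history=np.zeros((1, 1)), seed=0,
                           settings=SAEMSettings(), final_step_norm=0.0)
        iw = compute_iwres(fit)
        assert np.allclose(iw["iwres"], 0.0, atol=1e-9)

    def test_self_simulated_residuals_are_standard_normal(self):
        """IWRES at the generating parameters on self-simulated data follow
        N(0,1) closely (eta modes induce mild shrinkage, hence the modest
        KS threshold)."""
        spec = one_compartment_spec(omega_v=0.15, omega_k=0.1, a=20.0, b=0.08)
        data = simulate_study(tiny_iv_design(n=40), spec, None, seed=9)
        model = PopPKModel(data, spec)
        from rutinpk.estimation import _eta_modes
        modes = _eta_modes(model.engine, model.engine.layout.theta0)
        fit = PopPKResults(model=model, theta=model.engine.layout.theta0,
                           estimates={}, se={}, loglik=0.0, aic=0.0, n_free=0,
                           eta_modes=modes, history=np.zeros((1, 1)), seed=0,
                           settings=SAEMSettings(), final_step_norm=0.0)
        iw = compute_iwres(fit)["iwres"].to_numpy()
        assert len(iw) >= 400
        assert abs(np.mean(iw)) < 0.15
        assert kstest(iw, "norm").pvalue > 0.01

    def test_mismatched_data_rejected(self, iv_study, iv_model):
        model = PopPKModel(iv_study, iv_model)
        fit = PopPKResults(model=model, theta=model.engine.layout.theta0,
                           estimates={}, se={}, loglik=0.0, aic=0.0, n_free=0,
                           eta_modes=np.zeros((len(iv_study), 2)),
                           history=np.zeros((1, 1)), seed=0,
                           settings=SAEMSettings(), final_step_norm=0.0)
        with pytest.raises(EstimationError):
            compute_iwres(fit, iv_study[:-1])


class TestVPC:
    def test_bands_collapse_without_variability(self, iv_design):
        quiet = replace(iv_reference_model(),
                        random_effects=RandomEffectsSpec(sd={"V": 0.0, "k": 0.0}),
                        error=ResidualErrorModel(a=0.0, b=0.0))
        design = replace(iv_design, lloq=0.0)
        res = vpc(quiet, design, n_sim=50, seed=0)
        ok = res.bands.dropna()
        assert np.allclose(ok["p5"], ok["p95"], rtol=1e-9)

    def test_fixed_seed_reproduces_bands(self, iv_design, iv_model):
        a = vpc(iv_model, iv_design, n_sim=100, seed=3)
        b = vpc(iv_model, iv_design, n_sim=100, seed=3)
        assert a.bands.equals(b.bands)

    def test_band_ordering(self, iv_design, iv_model):
        res = vpc(iv_model, iv_design, n_sim=100, seed=1)
        ok = res.bands.dropna()
        assert np.all(ok["p5"] <= ok["p50"])
        assert np.all(ok["p50"] <= ok["p95"])

    def test_rejects_tiny_simulation_count(self, iv_design, iv_model):
        with pytest.raises(EstimationError):
            vpc(iv_model, iv_design, n_sim=1, seed=0)


class TestModelComparison:
    def _fit_stub(self, model, loglik, n_free):
        return PopPKResults(model=model, theta=model.engine.layout.theta0,
                            estimates={}, se={}, loglik=loglik,
                            aic=-2 * loglik + 2 * n_free, n_free=n_free,
                            eta_modes=np.zeros((2, 0)),
                            history=np.zeros((1, 1)), seed=0,
                            settings=SAEMSettings(), final_step_norm=0.0)

    def test_identical_fits_have_zero_delta(self, iv_study, iv_model):
        m = PopPKModel(iv_study, iv_model)
        fits = [self._fit_stub(m, -100.0, 5), self._fit_stub(m, -100.0, 5)]
        df = compare_models(fits)
        assert np.allclose(df["delta_aic"], 0.0)

    def test_aic_is_definitional(self, iv_study, iv_model):
        m = PopPKModel(iv_study, iv_model)
        fit = self._fit_stub(m, -123.4, 7)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 7)

    def test_different_data_rejected(self, iv_study, iv_model):
        m1 = PopPKModel(iv_study, iv_model)
        m2 = PopPKModel(iv_study[:-1], iv_model)
        with pytest.raises(EstimationError):
            compare_models([self._fit_stub(m1, -1.0, 1),
                            self._fit_stub(m2, -1.0, 1)])

    def test_combined_error_wins_on_combined_error_data(self):
        """Pooled (no-IIV) fits with combined, additive-only and
        proportional-only residual models on combined-error data: the
        combined form should win the AIC ranking in most replicates
        (scaled-down: pooled fits, 5 replicates, >= 4 wins)."""
        wins = 0
        for rep in range(5):
            truth = one_compartment_spec(omega_v=0.0, omega_k=0.0,
                                         a=25.0, b=0.12)
            data = simulate_study(tiny_iv_design(n=8), truth, None,
                                  seed=100 + rep)
            start = replace(truth,
                            random_effects=RandomEffectsSpec(sd={}),
                            error=ResidualErrorModel(a=10.0, b=0.05))
            fits = []
            for form, fix in (("combined", ()),
                              ("additive", ("b",)),
                              ("proportional", ("a",))):
                s = start
                if form == "additive":
                    s = replace(start, error=ResidualErrorModel(a=10.0, b=1e-6))
                elif form == "proportional":
                    s = replace(start, error=ResidualErrorModel(a=1e-3, b=0.05))
                fits.append(fit_population(data, s, seed=rep, settings=FAST,
                                           fix=fix, blq="exclude"))
            ranked = compare_models(fits)
            if ranked.iloc[0]["n_free"] == fits[0].n_free and (
                    ranked.iloc[0]["aic"] == pytest.approx(fits[0].aic)):
                wins += 1
        assert wins >= 4


class TestReferenceLevelInvariance:
    def test_reparameterised_reference_gives_same_individuals(self, iv_model):
        """Moving the reference level shifts the betas but leaves every
        individual's parameters (hence the likelihood) unchanged."""
        flipped = PopulationModel(
            structural="iv",
            fixed_effects={"V": iv_model.individual_parameters("GEXT").V,
                           "k": iv_model.individual_parameters("GEXT").k,
                           "k12": 2.6, "k21": 13.6},
            covariate_axis="source", levels=("GEXT", "RU"),
            effects=(CovariateEffect("V", "RU", -0.478),
                     CovariateEffect("k", "RU", -0.395)),
            random_effects=iv_model.random_effects,
            error=iv_model.error,
        )
        for level in ("RU", "GEXT"):
            a = iv_model.individual_parameters(level, np.array([0.1, -0.2]))
            b = flipped.individual_parameters(level, np.array([0.1, -0.2]))
            assert a.V == pytest.approx(b.V, rel=1e-9)
            assert a.k == pytest.approx(b.k, rel=1e-9)


class TestStandardErrors:
    def test_fisher_ses_are_finite_and_plausible(self):
        """Small self-simulated study: the Fisher step must deliver finite,
        positive SEs for the population values, with RSE consistent with
        the SE/estimate ratio."""
        spec = one_compartment_spec(omega_v=0.2, omega_k=0.15, a=20.0, b=0.08)
        data = simulate_study(tiny_iv_design(n=12), spec, None, seed=21)
        res = PopPKModel(data, spec).fit(
            seed=3, settings=SAEMSettings(n_burn=150, n_smooth=150))
        for name in ("V_pop", "k_pop"):
            assert np.isfinite(res.se[name]) and res.se[name] > 0
            assert res.rse[name] == pytest.approx(
                100 * res.se[name] / abs(res.estimates[name]))
            assert res.rse[name] < 60.0  # far tighter than the estimate scale
        table = res.summary()
        assert table.loc["V_pop", "value"] == pytest.approx(
            res.estimates["V_pop"])
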