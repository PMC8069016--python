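"""Structural-model tests: closed forms vs ODE integration, conservation
laws, dose linearity, and the double-peak behaviour of the oral model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rutinpk.structural import (
    ConcentrationProfile,
    DoseEvent,
    IVParameters,
    OralParameters,
    macro_constants,
    simulate_iv,
    simulate_iv_ode,
    simulate_oral,
    simulate_oral_ode,
)

IV_DOSE = DoseEvent(route="iv_bolus", amount=1.45)
IV_PARAMS = IVParameters(V=0.0646, k=1.47, k12=2.6, k21=13.6)
ORAL_PARAMS = OralParameters(ka1=0.104, ka2=0.411, F1=0.565, Tlag2=3.91,
                             V=13.2, k=1.42, k12=0.279, k21=0.268)


rates = st.floats(min_value=0.01, max_value=20.0)


class TestIV:
    def test_zero_dose_gives_zero_profile(self):
        prof = simulate_iv(IV_PARAMS, DoseEvent(route="iv_bolus", amount=0.0),
                           np.linspace(0, 12, 20))
        assert np.all(prof.values == 0.0)

    def test_initial_concentration_is_dose_over_volume(self):
        # 1000 * 1.45 / 0.0646 = 22445.8 ng/mL
        prof = simulate_iv(IV_PARAMS, IV_DOSE, np.array([0.0]))
        assert prof.values[0] == pytest.approx(22445.82, rel=1e-4)

    def test_auc_matches_dose_over_clearance(self):
        # closed form AUC = 1000*D/(V*k); quadrature of the simulated curve
        t = np.concatenate([np.linspace(0, 2, 4000, endpoint=False),
                            np.linspace(2, 400, 40000)])
        prof = simulate_iv(IV_PARAMS, IV_DOSE, t)
        auc = np.trapezoid(prof.values, prof.times)
        expected = 1000.0 * 1.45 / (0.0646 * 1.47)
        assert auc == pytest.approx(expected, rel=1e-3)
        assert expected == pytest.approx(15268.6, rel=1e-3)

    @given(V=st.floats(0.02, 5.0), k=rates, k12=rates, k21=rates)
    @settings(max_examples=30, deadline=None)
    def test_closed_form_matches_ode(self, V, k, k12, k21):
        params = IVParameters(V=V, k=k, k12=k12, k21=k21)
        t = np.linspace(0.05, 8.0, 40)
        a = simulate_iv(params, IV_DOSE, t).values
        b = simulate_iv_ode(params, IV_DOSE, t).values
        assert np.allclose(a, b, rtol=1e-6, atol=1e-9 * a.max())

    def test_dose_linearity(self):
        t = np.linspace(0.1, 12, 30)
        c1 = simulate_iv(IV_PARAMS, DoseEvent("iv_bolus", 1.45), t).values
        c2 = simulate_iv(IV_PARAMS, DoseEvent("iv_bolus", 2.9), t).values
        assert np.allclose(2.0 * c1, c2, rtol=1e-12)

    def test_rejects_wrong_route_and_bad_grid(self):
        with pytest.raises(ValueError):
            simulate_iv(IV_PARAMS, DoseEvent("oral", 1.0), [0, 1])
        with pytest.raises(ValueError):
            simulate_iv(IV_PARAMS, IV_DOSE, [])
        with pytest.raises(ValueError):
            simulate_iv(IV_PARAMS, IV_DOSE, [1.0, 0.5])

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            IVParameters(V=-0.1, k=1.0, k12=1.0, k21=1.0)


class TestMacroConstants:
    def test_sum_and_product_identities(self):
        alpha, beta, _, _ = macro_constants(IV_PARAMS)
        assert alpha >= beta > 0
        assert alpha + beta == pytest.approx(17.67, rel=1e-12)
        assert alpha * beta == pytest.approx(19.992, rel=1e-12)

    def test_decoupled_compartments(self):
        p = IVParameters(V=0.1, k=1.47, k12=0.0, k21=13.6)
        alpha, beta, _, _ = macro_constants(p)
        assert alpha == pytest.approx(13.6, rel=1e-9)
        assert beta == pytest.approx(1.47, rel=1e-9)

    @given(V=st.floats(0.02, 5.0), k=rates, k12=rates, k21=rates)
    @settings(max_examples=25, deadline=None)
    def test_biexponential_reconstruction_matches_ode(self, V, k, k12, k21):
        params = IVParameters(V=V, k=k, k12=k12, k21=k21)
        alpha, beta, A, B = macro_constants(params)
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0.01, 6.0, 50))
        recon = IV_DOSE.amount * (A * np.exp(-alpha * t) + B * np.exp(-beta * t))
        ode = simulate_iv_ode(params, IV_DOSE, t).values
        assert np.allclose(recon, ode, rtol=1e-6, atol=1e-9 * recon.max())


class TestOral:
    def test_closed_form_matches_ode(self):
        t = np.linspace(0.05, 24, 60)
        a = simulate_oral(ORAL_PARAMS, DoseEvent("oral", 100.0), t).values
        b = simulate_oral_ode(ORAL_PARAMS, DoseEvent("oral", 100.0), t).values
        assert np.allclose(a, b, rtol=1e-6, atol=1e-9 * a.max())

    def test_single_site_when_f1_is_one(self):
        t = np.linspace(0.1, 24, 50)
        base = dict(ka1=0.3, ka2=0.9, F1=1.0, V=10.0, k=0.8, k12=0.3, k21=0.4)
        c1 = simulate_oral(OralParameters(Tlag2=2.0, **base),
                           DoseEvent("oral", 50.0), t).values
        c2 = simulate_oral(OralParameters(Tlag2=9.0, **base),
                           DoseEvent("oral", 50.0), t).values
        assert np.allclose(c1, c2, rtol=1e-12)

    def test_mass_balance_without_elimination(self):
        # with k = 0 everything absorbed ends in the two compartments;
        # at equilibrium X1/(X1+X2) = k21/(k12+k21)
        p = OralParameters(ka1=0.5, ka2=0.7, F1=0.6, Tlag2=2.0,
                           V=10.0, k=0.0, k12=0.3, k21=0.6)
        dose = DoseEvent("oral", 50.0)
        c_inf = simulate_oral(p, dose, np.array([2000.0])).values[0]
        expected = 1000.0 * dose.amount * p.k21 / ((p.k12 + p.k21) * p.V)
        assert c_inf == pytest.approx(expected, rel=1e-5)

    def test_profile_before_lag_equals_single_depot(self):
        t = np.linspace(0.05, 3.8, 25)  # all before Tlag2 = 3.91
        full = simulate_oral(ORAL_PARAMS, DoseEvent("oral", 100.0), t).values
        # single-depot reduction: site 1 only, carrying F1 * dose
        single = simulate_oral(
            OralParameters(ka1=ORAL_PARAMS.ka1, ka2=ORAL_PARAMS.ka2, F1=1.0,
                           Tlag2=0.0, V=ORAL_PARAMS.V, k=ORAL_PARAMS.k,
                           k12=ORAL_PARAMS.k12, k21=ORAL_PARAMS.k21),
            DoseEvent("oral", 100.0 * ORAL_PARAMS.F1), t).values
        assert np.allclose(full, single, rtol=1e-10)

    def test_double_peak_with_published_values(self):
        t = np.linspace(0.05, 24, 960)
        prof = simulate_oral(ORAL_PARAMS, DoseEvent("oral", 100.0), t)
        d = np.diff(prof.values)
        peaks = [t[i + 1] for i in range(len(d) - 1) if d[i] > 0 and d[i + 1] <= 0]
        assert len(peaks) == 2
        assert peaks[1] > 3.91

    def test_lag_beyond_grid_is_valid(self):
        p = OralParameters(ka1=0.3, ka2=0.9, F1=0.5, Tlag2=48.0,
                           V=10.0, k=0.8, k12=0.3, k21=0.4)
        prof = simulate_oral(p, DoseEvent("oral", 50.0), np.linspace(0.1, 24, 10))
        assert np.all(np.isfinite(prof.values))

    @given(dose=st.floats(1.0, 500.0))
    @settings(max_examples=20, deadline=None)
    def test_nonnegative_and_dose_linear(self, dose):
        t = np.linspace(0.05, 24, 40)
        c = simulate_oral(ORAL_PARAMS, DoseEvent("oral", dose), t).values
        c2 = simulate_oral(ORAL_PARAMS, DoseEvent("oral", 2 * dose), t).values
        assert np.all(c >= 0)
        assert np.allclose(2 * c, c2, rtol=1e-12)


def test_profile_validation():
    with pytest.raises(ValueError):
        ConcentrationProfile(times=np.array([0.0, 0.0]), values=np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        ConcentrationProfile(times=np.array([0.0, 1.0]), values=np.array([1.0]))
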