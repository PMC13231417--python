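import dataclasses
import math

import numpy as np
import pytest

import mrnapk as mp
from mrnapk.errors import ConfigurationError, DegenerateSystemError
from mrnapk.reference import SCALING_FROM_MOUSE, SCALING_FROM_NHP

T = np.linspace(1.0, 1500.0, 60)


def bolus(amount, time=0.0, duration=0.0):
    return [mp.DoseEvent("s", time, amount, duration)]


class TestScaleParams:
    def test_unit_weight_identity(self, ribomab01):
        e = mp.scale_params(ribomab01, 1.0)
        assert e.k_elim == ribomab01.k_elim_mrna
        assert e.cl == ribomab01.cl_ab
        assert e.v2 == ribomab01.v2

    def test_human_effective_values(self, ribomab01):
        e = mp.scale_params(ribomab01, 70.0)
        assert e.cl == pytest.approx(8.031, abs=1e-3)
        assert e.k_elim == pytest.approx(0.02262, abs=1e-5)
        assert math.log(2) / e.k_elim == pytest.approx(30.6, abs=0.1)

    def test_nonpositive_weight_rejected(self, ribomab01):
        with pytest.raises(mp.ValidationError):
            mp.scale_params(ribomab01, 0.0)


class TestSimulate:
    def test_zero_dose_is_identically_zero(self, ribomab01):
        prof = mp.simulate(ribomab01, 2.5, [], T)
        assert np.all(prof.concentration == 0.0)

    def test_dose_linearity(self, ribomab01):
        p1 = mp.simulate(ribomab01, 2.5, bolus(50.0), T)
        p2 = mp.simulate(ribomab01, 2.5, bolus(100.0), T)
        np.testing.assert_allclose(p2.concentration, 2 * p1.concentration,
                                   rtol=1e-9)
        assert p2.dcmax() == pytest.approx(p1.dcmax(), rel=1e-9)

    @pytest.mark.parametrize("w", [0.025, 2.5, 70.0])
    def test_expm_matches_closed_form(self, ribomab01, w):
        sim = mp.simulate(ribomab01, w, bolus(100.0), T)
        cf = mp.closed_form_profile(ribomab01, w, 100.0, times=T)
        np.testing.assert_allclose(sim.concentration, cf, rtol=1e-6)

    def test_ivp_matches_closed_form(self, ribomab01):
        sim = mp.simulate(ribomab01, 2.5, bolus(100.0), T, method="ivp")
        cf = mp.closed_form_profile(ribomab01, 2.5, 100.0, times=T)
        np.testing.assert_allclose(sim.concentration, cf, rtol=1e-5)

    def test_one_compartment_variant(self, ribomab02):
        sim = mp.simulate(ribomab02, 2.5, bolus(100.0), T)
        cf = mp.closed_form_profile(ribomab02, 2.5, 100.0, times=T)
        np.testing.assert_allclose(sim.concentration, cf, rtol=1e-6)
        assert sim.states.shape[1] == 2

    def test_superposition_of_multiple_doses(self, ribomab01):
        t = np.linspace(0.0, 2000.0, 80)
        multi = mp.simulate(
            ribomab01, 2.5,
            [mp.DoseEvent("s", 0.0, 100.0), mp.DoseEvent("s", 336.0, 100.0)], t
        )
        single0 = mp.closed_form_profile(ribomab01, 2.5, 100.0)
        expected = single0(t) + single0(t - 336.0)
        np.testing.assert_allclose(multi.concentration, expected,
                                   rtol=1e-8, atol=1e-14)

    def test_infusion_preserves_exposure(self, ribomab01):
        # total AUC is duration-independent in a linear system
        t = np.linspace(0.0, 30000.0, 4000)
        inf = mp.simulate(ribomab01, 2.5, bolus(100.0, duration=2.0), t)
        a_inf, _, _ = mp.auc_inf((t[1:], inf.concentration[1:]))
        assert a_inf / 100.0 == pytest.approx(
            mp.closed_form_dauc(ribomab01, 2.5), rel=5e-3
        )

    def test_states_nonnegative(self, ribomab01):
        regimen = [
            mp.DoseEvent("s", 0.0, 50.0, 1.0),
            mp.DoseEvent("s", 168.0, 100.0),
            mp.DoseEvent("s", 336.0, 25.0, 6.0),
        ]
        prof = mp.simulate(ribomab01, 70.0, regimen, np.linspace(0, 3000, 200))
        assert np.all(prof.states >= 0.0)
        assert np.all(prof.concentration >= 0.0)

    def test_unsorted_times_rejected(self, ribomab01):
        with pytest.raises(mp.ValidationError):
            mp.simulate(ribomab01, 2.5, bolus(1.0), [2.0, 1.0])


class TestClosedForms:
    def test_dauc_reference_value(self, ribomab01):
        assert mp.closed_form_dauc(ribomab01, 70.0) == pytest.approx(
            0.2392, abs=2e-4
        )

    def test_dauc_proportional_to_k_translate(self, ribomab01):
        doubled = dataclasses.replace(ribomab01,
                                      k_translate=2 * ribomab01.k_translate)
        assert mp.closed_form_dauc(doubled, 2.5) == pytest.approx(
            2 * mp.closed_form_dauc(ribomab01, 2.5), rel=1e-12
        )

    def test_dauc_independent_of_volumes_and_q(self, ribomab01):
        moved = dataclasses.replace(ribomab01, v1=99.0, v2=7.0, q_ab=3.3)
        assert mp.closed_form_dauc(moved, 2.5) == pytest.approx(
            mp.closed_form_dauc(ribomab01, 2.5), rel=1e-12
        )

    def test_numeric_dauc_matches_closed_form(self, ribomab01):
        # simulate far into the terminal phase, extrapolate the remainder
        t = np.linspace(0.0, 20000.0, 3000)
        prof = mp.simulate(ribomab01, 70.0, bolus(100.0), t)
        a_inf, _, _ = mp.auc_inf((t[1:], prof.concentration[1:]))
        assert a_inf / 100.0 == pytest.approx(
            mp.closed_form_dauc(ribomab01, 70.0), rel=5e-3
        )

    def test_concentration_zero_at_dose_time(self, ribomab01):
        cf = mp.closed_form_profile(ribomab01, 2.5, 100.0)
        assert cf(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_vanishing_translation_gives_zero_profile(self, ribomab01):
        small = dataclasses.replace(ribomab01, k_translate=1e-12)
        cf = mp.closed_form_profile(small, 2.5, 100.0)
        assert np.all(np.abs(cf(T)) < 1e-8)

    def test_degenerate_eigenvalues_refused(self):
        # 1-compartment with k_elim exactly equal to CL/V1
        p = mp.TranslationalParams(
            k_elim_mrna=0.05, alpha_k_elim=0.0, k_translate=0.1,
            alpha_k_translate=0.0, cl_ab=0.5, alpha_cl=0.0, v1=10.0,
            alpha_v1=0.0,
        )
        with pytest.raises(DegenerateSystemError):
            mp.closed_form_profile(p, 1.0, 100.0)


class TestProjection:
    def test_identity_when_weights_equal(self, ribomab01):
        proj = mp.project_params_cross_species(ribomab01, 2.5, 2.5,
                                               SCALING_FROM_NHP)
        e = mp.scale_params(ribomab01, 2.5)
        assert proj.k_translate == pytest.approx(e.k_translate, rel=1e-12)
        assert proj.cl_ab == pytest.approx(e.cl, rel=1e-12)

    def test_nhp_translation_rate_not_adjusted(self, ribomab01):
        proj = mp.project_params_cross_species(ribomab01, 2.5, 70.0,
                                               SCALING_FROM_NHP)
        e = mp.scale_params(ribomab01, 2.5)
        assert proj.k_translate == pytest.approx(e.k_translate, rel=1e-12)

    def test_mouse_clearance_multiplier(self, ribomab01):
        proj = mp.project_params_cross_species(ribomab01, 0.025, 70.0,
                                               SCALING_FROM_MOUSE)
        e = mp.scale_params(ribomab01, 0.025)
        assert proj.cl_ab / e.cl == pytest.approx(2800.0**0.80, rel=1e-12)
        assert proj.cl_ab / e.cl == pytest.approx(573.6, rel=5e-3)
        assert proj.k_translate / e.k_translate == pytest.approx(
            2800.0**-0.51, rel=1e-12
        )

    def test_missing_exponent_raises(self, ribomab01):
        incomplete = mp.ScalingConfig(exponents={"cl_ab": 0.8})
        with pytest.raises(ConfigurationError):
            mp.project_params_cross_species(ribomab01, 2.5, 70.0, incomplete)


class TestPopulationBands:
    def test_zero_omega_bands_collapse_to_typical(self, ribomab01):
        out = mp.simulate_population(ribomab01, 2.5, bolus(100.0), T,
                                     n_replicates=10, seed=1)
        np.testing.assert_array_equal(out["bands"][0], out["typical"])

    def test_bands_ordered_and_deterministic(self, ribomab01):
        p = dataclasses.replace(ribomab01,
                                omega={"cl_ab": 0.3, "k_translate": 0.25})
        out1 = mp.simulate_population(p, 2.5, bolus(100.0), T,
                                      n_replicates=60, seed=9)
        out2 = mp.simulate_population(p, 2.5, bolus(100.0), T,
                                      n_replicates=60, seed=9)
        np.testing.assert_array_equal(out1["bands"], out2["bands"])
        assert np.all(out1["bands"][0] <= out1["bands"][1] + 1e-15)
        assert np.all(out1["bands"][1] <= out1["bands"][2] + 1e-15)
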