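"""Agonist mapping, Hill adhesiveness, activation integral, thrombin curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thrombosim.geometry import ConfigurationError
from thrombosim.signaling import (CONVULXIN_CONTACT_NM, U46619_PER_TXA2,
                                  ActivationState, CalciumTrace, HillParams,
                                  ThrombinParams, assemble_agonist_inputs,
                                  hill_adhesiveness, thrombin_curve,
                                  update_activation)


class TestAgonistMapping:
    def test_txa2_maps_to_u46619_equivalents(self):
        v = assemble_agonist_inputs(0.0, 2.0, False, 0.0, "control")
        assert v.u46619 == pytest.approx(U46619_PER_TXA2 * 2.0)  # 15x

    def test_collagen_contact_injects_convulxin(self):
        v = assemble_agonist_inputs(0.0, 0.0, True, 0.0, "control")
        assert v.convulxin == CONVULXIN_CONTACT_NM  # 10 nM
        assert assemble_agonist_inputs(0.0, 0.0, False, 0.0,
                                       "control").convulxin == 0.0

    @pytest.mark.parametrize("scenario,zeroed", [
        ("no-adp", ("adp",)),
        ("no-txa2", ("u46619",)),
        ("no-both", ("adp", "u46619")),
    ])
    def test_inhibition_scenarios_zero_inputs(self, scenario, zeroed):
        v = assemble_agonist_inputs(5.0, 1.0, True, 0.0, scenario)
        for name in zeroed:
            assert getattr(v, name) == 0.0
        untouched = {"adp", "u46619"} - set(zeroed)
        for name in untouched:
            assert getattr(v, name) > 0.0

    def test_antagonist_scenarios_set_constant_dose(self):
        assert assemble_agonist_inputs(0, 0, False, 0, "iloprost").iloprost > 0
        assert assemble_agonist_inputs(0, 0, False, 0, "gsno").gsno > 0
        ctrl = assemble_agonist_inputs(0, 0, False, 0, "control")
        assert ctrl.iloprost == ctrl.gsno == 0.0

    def test_thrombin_only_in_tf_scenario(self):
        assert assemble_agonist_inputs(0, 0, False, 7.0, "tf").thrombin == 7.0
        assert assemble_agonist_inputs(0, 0, False, 7.0, "control").thrombin == 0.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigurationError):
            assemble_agonist_inputs(0, 0, False, 0, "aspirin")

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            assemble_agonist_inputs(-1.0, 0, False, 0, "control")


class TestHill:
    def test_zero_activation_gives_alpha_min(self):
        p = HillParams()
        assert hill_adhesiveness(0.0, p) == pytest.approx(p.alpha_min)

    def test_midpoint_identity(self):
        p = HillParams(xi50=7.0)
        assert hill_adhesiveness(7.0, p) == pytest.approx(
            (p.alpha_min + p.alpha_max) / 2)

    @given(st.floats(-100, 1e4), st.floats(-100, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, a, b):
        p = HillParams(xi50=12.0)
        fa, fb = hill_adhesiveness(a, p), hill_adhesiveness(b, p)
        assert p.alpha_min - 1e-12 <= fa <= p.alpha_max + 1e-12
        if a <= b:
            assert fa <= fb + 1e-12

    def test_sharpness_parameter_steepens_response(self):
        lo = HillParams(n=1.0)
        hi = HillParams(n=4.0)
        x = np.array([0.5, 2.0]) * lo.xi50
        f_lo = [hill_adhesiveness(v, lo) for v in x]
        f_hi = [hill_adhesiveness(v, hi) for v in x]
        assert f_hi[0] < f_lo[0] and f_hi[1] > f_lo[1]


class TestActivation:
    def test_constant_excursion_integral(self):
        # [Ca] = ca0 + c for T seconds -> xi = c T
        p = HillParams(xi_crit=1e9)
        s = ActivationState(xi=0.0)
        for t in range(100):
            update_activation(s, 0.15, 0.05, float(t), 1.0, p)
        assert s.xi == pytest.approx(0.1 * 100)

    def test_basal_trace_accumulates_nothing(self):
        p = HillParams()
        s = ActivationState(xi=0.0)
        for t in range(50):
            update_activation(s, 0.05, 0.05, float(t), 1.0, p)
        assert s.xi == 0.0
        assert s.F == pytest.approx(p.alpha_min)
        assert not s.released

    def test_negative_excursions_subtract(self):
        p = HillParams(xi_crit=1e9)
        s = ActivationState(xi=5.0)
        update_activation(s, 0.01, 0.05, 0.0, 1.0, p)
        assert s.xi == pytest.approx(5.0 - 0.04)

    def test_release_flag_is_monotone(self):
        p = HillParams(xi_crit=1.0)
        s = ActivationState(xi=0.0)
        update_activation(s, 2.0, 0.05, 3.0, 1.0, p)
        assert s.released and s.t_release == 3.0
        update_activation(s, 0.0, 0.05, 4.0, 1.0, p)  # xi falls back
        assert s.released and s.t_release == 3.0


class TestCalciumTrace:
    def test_pre_entry_lags_return_basal(self):
        tr = CalciumTrace(ca0=0.05, t_entry=100.0)
        tr.append(0.2)
        tr.append(0.3)
        assert tr.at(99.0) == 0.05    # before entry
        assert tr.at(100.0) == 0.2
        assert tr.at(101.0) == 0.3
        lags = tr.lag_vector(101.0)
        assert lags[0] == 0.2         # t - 1
        assert all(v == 0.05 for v in lags[1:])


class TestThrombinCurve:
    def test_no_tissue_factor_no_thrombin(self):
        assert all(thrombin_curve(t, 0.0) == 0.0 for t in (0, 50, 400))

    def test_zero_at_time_zero(self):
        assert thrombin_curve(0.0, 1.0) == 0.0

    def test_monotone_in_time_and_tf_density(self):
        # brute-force sweep of the surrogate curve
        times = np.linspace(0, 600, 121)
        rhos = [0.1, 0.5, 1.0, 3.0]
        curves = np.array([[thrombin_curve(t, r) for t in times] for r in rhos])
        assert (np.diff(curves, axis=1) >= -1e-12).all()   # in t
        assert (np.diff(curves, axis=0) >= -1e-12).all()   # in rho

    def test_lag_phase_shortens_with_tf(self):
        p = ThrombinParams()
        t_first = []
        for rho in (0.2, 2.0):
            t = next(t for t in np.arange(0, 400, 1.0)
                     if thrombin_curve(t, rho, p) > 0)
            t_first.append(t)
        assert t_first[1] < t_first[0]

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            thrombin_curve(10.0, -1.0)


class TestPredictCalcium:
    def test_resting_platelet_stays_basal(self, one_donor_model):
        from thrombosim.signaling import AgonistVector, predict_calcium
        tr = CalciumTrace(ca0=one_donor_model.ca0, t_entry=0.0)
        for t in range(5):
            tr.append(one_donor_model.ca0)
        ca = predict_calcium(one_donor_model, tr, AgonistVector(), 4.0)
        assert ca == pytest.approx(one_donor_model.ca0, abs=0.05)

    def test_collagen_contact_raises_calcium(self, one_donor_model):
        from thrombosim.signaling import AgonistVector, predict_calcium
        from thrombosim.donors import rollout
        trace = rollout(one_donor_model, {"convulxin": 10.0}, 80)
        tr = CalciumTrace(ca0=one_donor_model.ca0, t_entry=0.0)
        for v in trace:
            tr.append(v)
        ca = predict_calcium(one_donor_model, tr,
                             AgonistVector(convulxin=10.0), 79.0)
        assert ca > one_donor_model.ca0 + 0.05


class TestDonorModelSerialization:
    def test_h5_round_trip(self, tmp_path, one_donor_model):
        import h5py

        from thrombosim.signaling import DonorModel
        path = tmp_path / "donor.h5"
        with h5py.File(path, "w") as h5:
            one_donor_model.save(h5.create_group("d"))
        with h5py.File(path, "r") as h5:
            back = DonorModel.load(h5["d"])
        X = np.random.default_rng(0).random((5, 14))
        assert np.allclose(back.predict(X), one_donor_model.predict(X))
        assert back.ca0 == one_donor_model.ca0
        assert back.hill == one_donor_model.hill

    def test_prediction_is_pure(self, one_donor_model):
        X = np.random.default_rng(1).random((3, 14))
        assert np.array_equal(one_donor_model.predict(X),
                              one_donor_model.predict(X))

    def test_prediction_nonnegative(self, one_donor_model):
        X = np.random.default_rng(2).random((50, 14)) * 10
        assert (one_donor_model.predict(X) >= 0).all()
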