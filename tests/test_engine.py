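"""ODE engine: conservation, closed-form limits, linearity, profile I/O."""
import numpy as np
import pytest
from scipy.linalg import expm

from cefepime_pbpk.distribution import cefepime_defaults
from cefepime_pbpk.engine import (
    ConcentrationTimeProfile,
    DoseRegimen,
    _system_matrix,
    assemble_model,
    default_output_times,
    mass_balance,
    read_profile,
    simulate,
    write_profile,
)
from cefepime_pbpk.physiology import IndividualPhysiology, OrganSpec


def _simulate(model, dose_mg, duration_min=30, horizon=12.0, full=False):
    regimen = DoseRegimen(dose_mg=dose_mg, infusion_duration_min=duration_min)
    return simulate(model, regimen, default_output_times(horizon), full_output=full)


class TestConservation:
    def test_zero_dose_stays_zero(self, adult_model):
        result = _simulate(adult_model, 0.0, full=True)
        assert np.all(result.states == 0.0)
        assert np.all(result.profile.concentrations == 0.0)
        assert mass_balance(adult_model, result) == 0.0

    def test_mass_balance_at_solver_tolerance(self, adult_model, healthy_2000mg_result):
        assert mass_balance(adult_model, healthy_2000mg_result) <= 1e-6

    def test_no_elimination_conserves_total_amount(self, reference_adult, adult_kps):
        import dataclasses

        drug0 = dataclasses.replace(cefepime_defaults(), renal_clearance_ml_min_kg=0.0)
        model = assemble_model(reference_adult, drug0, adult_kps)
        result = _simulate(model, 1000.0, full=True)
        after_infusion = result.profile.times >= 0.5
        body = result.states[:-1, :].sum(axis=0)
        assert result.states[-1, -1] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(body[after_infusion], 1000.0, rtol=1e-6)


class TestAgainstClosedForms:
    def test_steady_state_infusion(self, adult_model):
        # Css = rate / CL for a constant-rate infusion run to steady state
        rate_mg_h = 100.0
        regimen = DoseRegimen(dose_mg=rate_mg_h * 60.0, infusion_duration_min=60 * 60.0)
        times = default_output_times(60.0, dt_h=0.25)
        profile = simulate(adult_model, regimen, times)
        css = rate_mg_h / adult_model.cl_plasma
        assert profile.concentrations[-1] == pytest.approx(css, rel=5e-3)

    def test_matrix_exponential_oracle(self, adult_model):
        # piecewise-constant input: the augmented matrix exponential is the
        # exact solution of the linear system
        dose, dur_h = 1000.0, 0.5
        a = _system_matrix(adult_model)
        n = a.shape[0]
        u = np.zeros(n)
        u[1] = dose / dur_h  # venous pool receives the infusion
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = a
        aug[:n, n] = u
        x_end_inf = (expm(aug * dur_h) @ np.concatenate([np.zeros(n), [1.0]]))[:n]
        check_times = [1.0, 2.0, 6.0]
        profile = simulate(
            adult_model, DoseRegimen(dose_mg=dose, infusion_duration_min=30),
            np.array([0.0, dur_h] + check_times),
        )
        for i, t in enumerate(check_times):
            exact = expm(a * (t - dur_h)) @ x_end_inf
            c_exact = exact[1] / adult_model.v_ven / adult_model.bp
            assert profile.concentrations[2 + i] == pytest.approx(c_exact, rel=1e-6)

    def test_one_compartment_collapse(self):
        # a single fast-perfused organ behaves as one well-stirred
        # compartment; the closed-form infusion solution is the oracle
        v_tissue, q_blood = 15.0, 20000.0  # L, L/min: flow >> CL forces the well-stirred limit
        organs = (
            OrganSpec("kidney", v_tissue, q_blood, "kidney"),
            OrganSpec("lung", 0.01, float("nan"), "lung"),
            OrganSpec("arterial_blood", 0.01, float("nan"), "blood"),
            OrganSpec("venous_blood", 0.01, float("nan"), "blood"),
        )
        phys = IndividualPhysiology(
            organs=organs, body_weight=70.0, height=180.0, age=30.0, sex="male",
            hematocrit=0.45, gfr=120.0, cardiac_output=q_blood,
        )
        drug = cefepime_defaults()
        model = assemble_model(phys, drug, {"kidney": 1.0, "lung": 1.0})
        cl = model.cl_plasma  # 8.82 L/h
        bp = model.bp
        v_eff = v_tissue + 0.01 + 0.02 * bp  # plasma-equivalent volume
        k = cl / v_eff

        dose, dur = 1000.0, 0.5
        rate = dose / dur
        times = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
        profile = simulate(
            model, DoseRegimen(dose_mg=dose, infusion_duration_min=30), times
        )
        for t, c in zip(times, profile.concentrations):
            if t <= dur:
                expected = rate / cl * (1.0 - np.exp(-k * t))
            else:
                c_end = rate / cl * (1.0 - np.exp(-k * dur))
                expected = c_end * np.exp(-k * (t - dur))
            assert c == pytest.approx(expected, rel=1e-3)


class TestLinearity:
    def test_superposition_in_dose(self, adult_model):
        low = _simulate(adult_model, 500.0)
        high = _simulate(adult_model, 1000.0)
        mask = low.concentrations > 1e-6
        assert np.allclose(
            high.concentrations[mask], 2.0 * low.concentrations[mask], rtol=1e-6
        )

    @pytest.mark.parametrize("dose", [62.5, 500.0, 2000.0])
    def test_dose_over_auc_equals_clearance(self, adult_model, dose):
        from cefepime_pbpk.nca import auc_to_infinity

        profile = _simulate(adult_model, dose)
        auc_inf, _, _ = auc_to_infinity(profile)
        assert dose / auc_inf == pytest.approx(adult_model.cl_plasma, rel=0.02)

    def test_terminal_slope_dose_independent(self, adult_model):
        from cefepime_pbpk.nca import terminal_slope

        slopes = [
            terminal_slope(_simulate(adult_model, dose)).lambda_z
            for dose in (62.5, 2000.0)
        ]
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-6)

    def test_shorter_infusion_raises_cmax(self, adult_model):
        cmaxes = [
            _simulate(adult_model, 2000.0, duration_min=dur).concentrations.max()
            for dur in (30, 15, 5, 3)
        ]
        assert all(b > a for a, b in zip(cmaxes, cmaxes[1:]))


class TestAssembly:
    def test_missing_kp_rejected(self, reference_adult, drug, adult_kps):
        incomplete = {k: v for k, v in adult_kps.items() if k != "liver"}
        with pytest.raises(ValueError, match="liver"):
            assemble_model(reference_adult, drug, incomplete)

    def test_clearance_is_weight_specific(self, adult_model):
        assert adult_model.cl_plasma == pytest.approx(2.1 * 70 * 0.06)

    def test_invalid_regimen(self):
        with pytest.raises(ValueError):
            DoseRegimen(dose_mg=1000, dose_mg_per_kg=50)
        with pytest.raises(ValueError):
            DoseRegimen(dose_mg=1000, infusion_duration_min=0)


class TestProfileIO:
    def test_round_trip(self, tmp_path, healthy_2000mg_profile):
        path = tmp_path / "profile.tsv"
        write_profile(healthy_2000mg_profile, path)
        loaded = read_profile(path)
        assert np.allclose(loaded.times, healthy_2000mg_profile.times)
        assert np.allclose(
            loaded.concentrations, healthy_2000mg_profile.concentrations, rtol=1e-6
        )
        assert loaded.metadata["dose_mg"] == 2000

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            ConcentrationTimeProfile(np.array([0.0, 0.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            ConcentrationTimeProfile(np.array([0.0, 1.0]), np.array([1.0, np.inf]))
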