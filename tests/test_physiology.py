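"""Physiology construction and disease/age transforms."""
import pytest
from hypothesis import given, strategies as st

from cefepime_pbpk.physiology import (
    DiseaseModifierSet,
    apply_moderate_ckd,
    apply_obesity,
    apply_pediatric,
    apply_severe_ckd,
    build_reference_adult,
    du_bois_bsa,
)


class TestReferenceAdult:
    def test_defaults(self, reference_adult):
        assert reference_adult.gfr == 120.0
        assert reference_adult.protein_binding_factor == 1.0
        assert reference_adult.hematocrit == 0.45
        assert build_reference_adult(70, 180, 30, "female").hematocrit == 0.40

    def test_unit_density_closure(self, reference_adult):
        assert reference_adult.total_volume == pytest.approx(70.0, rel=0.05)

    def test_linear_volume_scaling(self, reference_adult):
        heavy = build_reference_adult(140.0, 180.0, 30.0, "male")
        for organ in reference_adult.organs:
            assert heavy.organ(organ.name).volume == pytest.approx(2.0 * organ.volume, rel=1e-12)

    def test_flow_sum_matches_cardiac_output(self, reference_adult):
        assert reference_adult.perfusion_sum == pytest.approx(
            reference_adult.cardiac_output, rel=1e-12
        )

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(weight=10, height=180, age=30), "weight"),
            (dict(weight=70, height=80, age=30), "height"),
            (dict(weight=70, height=180, age=10), "age"),
            (dict(weight=300, height=180, age=30), "weight"),
        ],
    )
    def test_out_of_bounds_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            build_reference_adult(sex="male", **kwargs)


class TestDuBois:
    def test_reference_values(self):
        # frozen from direct evaluation of 0.007184 * w^0.425 * h^0.725
        assert du_bois_bsa(70, 180) == pytest.approx(1.886, abs=5e-4)
        assert du_bois_bsa(130, 170) == pytest.approx(2.354, abs=5e-4)
        assert du_bois_bsa(1, 1) == pytest.approx(0.007184, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            du_bois_bsa(0, 170)
        with pytest.raises(ValueError):
            du_bois_bsa(70, -1)

    @given(
        w=st.floats(min_value=3, max_value=200),
        h=st.floats(min_value=50, max_value=220),
        dw=st.floats(min_value=0.5, max_value=20),
        dh=st.floats(min_value=0.5, max_value=20),
    )
    def test_strictly_increasing(self, w, h, dw, dh):
        base = du_bois_bsa(w, h)
        assert du_bois_bsa(w + dw, h) > base
        assert du_bois_bsa(w, h + dh) > base


class TestCKDTransforms:
    def test_moderate_values(self, reference_adult):
        mod = apply_moderate_ckd(reference_adult)
        assert mod.gastric_emptying_time == 20.625
        assert mod.protein_binding_factor == 0.9265
        assert mod.hematocrit == 0.433
        assert mod.gfr == pytest.approx(45.5)
        # moderate disease does not touch renal blood flow
        assert mod.renal_blood_flow == reference_adult.renal_blood_flow
        assert mod.organ("kidney").blood_flow == reference_adult.organ("kidney").blood_flow

    def test_severe_values(self, reference_adult):
        sev = apply_severe_ckd(reference_adult)
        assert sev.gastric_emptying_time == 24.375
        assert sev.hematocrit == 0.398
        assert sev.protein_binding_factor == 0.837
        assert sev.renal_blood_flow == 0.17
        assert sev.hepatic_arterial_blood_flow == 0.16
        assert sev.organ("kidney").blood_flow == 0.17
        assert sev.organ("liver").blood_flow == 0.16
        assert sev.gfr == pytest.approx(20.5)

    def test_hct_ordering_across_severity(self, reference_adult):
        mod = apply_moderate_ckd(reference_adult)
        sev = apply_severe_ckd(reference_adult)
        assert sev.hematocrit < mod.hematocrit < reference_adult.hematocrit

    def test_input_physiology_unchanged(self, reference_adult):
        before = reference_adult.to_dict()
        apply_moderate_ckd(reference_adult)
        apply_severe_ckd(reference_adult)
        assert reference_adult.to_dict() == before

    def test_double_application_guard(self, reference_adult):
        mod = apply_moderate_ckd(reference_adult)
        with pytest.raises(ValueError, match="healthy"):
            apply_moderate_ckd(mod)
        with pytest.raises(ValueError, match="healthy"):
            apply_severe_ckd(mod)

    def test_gfr_band_enforced(self, reference_adult):
        with pytest.raises(ValueError):
            apply_moderate_ckd(reference_adult, gfr=80.0)
        with pytest.raises(ValueError):
            apply_severe_ckd(reference_adult, gfr=5.0)


@pytest.fixture(scope="module")
def obese():
    return apply_obesity(build_reference_adult(130.0, 170.0, 45.0, "male"))


class TestObesity:
    def test_gfr_scales_with_bsa(self, obese):
        assert obese.gfr == pytest.approx(143.0 * du_bois_bsa(130, 170) / 1.73)

    def test_hct_and_binding_unchanged(self, obese):
        base = build_reference_adult(130.0, 170.0, 45.0, "male")
        assert obese.hematocrit == base.hematocrit
        assert obese.protein_binding_factor == base.protein_binding_factor

    def test_excess_weight_goes_to_adipose(self, obese):
        assert obese.total_volume == pytest.approx(130.0, rel=0.05)
        lean = build_reference_adult(72.25, 170.0, 45.0, "male")
        assert obese.organ("adipose").volume > lean.organ("adipose").volume
        assert obese.organ("muscle").volume == pytest.approx(
            lean.organ("muscle").volume, rel=1e-6
        )

    def test_clearance_referenced_to_normal_weight(self, obese):
        assert obese.effective_clearance_weight == pytest.approx(25.0 * 1.70**2)

    def test_non_obese_bmi_warns(self):
        slim = build_reference_adult(70.0, 180.0, 30.0, "male")
        with pytest.warns(UserWarning, match="BMI"):
            apply_obesity(slim)


class TestPediatric:
    def test_literature_flows_at_reference_size(self, reference_adult):
        ped = apply_pediatric(reference_adult, age=17.0, weight=70.0)
        assert ped.organ("brain").blood_flow == pytest.approx(1.85)
        assert ped.organ("kidney").blood_flow == pytest.approx(1.4)
        assert ped.organ("small_intestine").blood_flow == pytest.approx(1.4)

    def test_allometric_flow_scaling(self, reference_adult):
        ped = apply_pediatric(reference_adult, age=11.0, weight=35.0)
        assert ped.organ("kidney").blood_flow == pytest.approx(1.4 * 0.5**0.75, rel=1e-12)
        assert ped.gfr == pytest.approx(120.0 * 0.5**0.75, rel=1e-12)

    def test_volumes_linear_in_weight(self, reference_adult):
        ped = apply_pediatric(reference_adult, age=11.0, weight=35.0)
        assert ped.total_volume == pytest.approx(35.0, rel=0.05)

    def test_age_bounds(self, reference_adult):
        with pytest.raises(ValueError, match="age"):
            apply_pediatric(reference_adult, age=0.05, weight=4.0)
        with pytest.raises(ValueError, match="age"):
            apply_pediatric(reference_adult, age=20.0, weight=60.0)


class TestModifierSet:
    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            DiseaseModifierSet(overrides={"plasma_sodium": 140.0})

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            DiseaseModifierSet(multipliers={"hematocrit": 0.0})

    def test_apply_override_and_multiplier(self, reference_adult):
        mods = DiseaseModifierSet(
            overrides={"gastric_emptying_time": 24.375},
            multipliers={"hematocrit": 0.9},
        )
        out = mods.apply(reference_adult)
        assert out.gastric_emptying_time == 24.375
        assert out.hematocrit == pytest.approx(0.45 * 0.9)
        assert reference_adult.hematocrit == 0.45
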