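"""Reference-adult physiology and its pediatric, renal-impairment and obesity variants.

The model individual is a set of perfused organs (volume, blood flow,
tissue-composition key) plus whole-body covariates: hematocrit (HCT),
glomerular filtration rate (GFR), plasma protein binding factor (PBF,
scaling of binding-protein concentration relative to healthy), gastric
emptying time (GET), renal and hepatic-arterial blood flow (RBF, HABF).
Disease transforms are pure functions returning a new individual; the
input is never mutated.

Organ volumes and flows for the 70 kg reference man are ICRP-style
literature values (ICRP Publication 89; Brown et al. 1997, Toxicol Ind
Health 13:407) and are linearly rescaled so that total volume matches
body weight at unit density.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
__all__ = [
    "OrganSpec",
    "IndividualPhysiology",
    "PopulationDemographics",
    "DiseaseModifierSet",
    "build_reference_adult",
    "du_bois_bsa",
    "apply_moderate_ckd",
    "apply_severe_ckd",
    "apply_obesity",
    "apply_pediatric",
    "SPLANCHNIC_ORGANS",
    "HEALTHY_ADULT_GFR_ML_MIN",
]

#: organs whose venous outflow drains into the portal vein (then liver)
SPLANCHNIC_ORGANS = ("spleen", "stomach", "small_intestine", "large_intestine", "pancreas")

#: healthy-adult GFR reference used to express renal function as a fraction
HEALTHY_ADULT_GFR_ML_MIN = 120.0

# name -> (volume L, blood flow L/min, composition key) at 70 kg reference.
# The liver flow is the hepatic *arterial* flow; portal inflow is the sum of
# the splanchnic flows. Blood pool rows carry no flow/composition.
_REFERENCE_ORGANS: dict[str, tuple[float, float, str]] = {
    "lung": (0.53, float("nan"), "lung"),  # perfused by total cardiac output
    "heart": (0.33, 0.26, "heart"),
    "brain": (1.45, 0.78, "brain"),
    "muscle": (29.0, 1.10, "muscle"),
    "skin": (3.30, 0.30, "skin"),
    "adipose": (18.2, 0.33, "adipose"),
    "bone": (10.5, 0.35, "bone"),
    "liver": (1.80, 0.43, "liver"),
    "spleen": (0.15, 0.077, "spleen"),
    "stomach": (0.15, 0.038, "gut"),
    "small_intestine": (0.64, 0.60, "gut"),
    "large_intestine": (0.37, 0.24, "gut"),
    "pancreas": (0.10, 0.058, "pancreas"),
    "kidney": (0.31, 1.24, "kidney"),
    "gonads": (0.035, 0.003, "gonads"),
    "rest_of_body": (1.10, 0.26, "rest"),
    "arterial_blood": (1.70, float("nan"), "blood"),
    "venous_blood": (3.90, float("nan"), "blood"),
}

_BLOOD_POOLS = ("arterial_blood", "venous_blood")
_REFERENCE_WEIGHT_KG = 70.0

# Pediatric organ blood flows (L/min) at 70 kg-equivalent size, rescaled by
# (weight/70)^0.75 when applied to an individual child.
PEDIATRIC_FLOWS_L_MIN: dict[str, float] = {
    "large_intestine": 0.43,
    "heart": 0.35,
    "liver": 0.53,
    "spleen": 0.29,
    "skin": 0.23,
    "small_intestine": 1.4,
    "stomach": 0.10,
    "pancreas": 0.08,
    "muscle": 0.88,
    "kidney": 1.4,
    "brain": 1.85,
}

MODERATE_CKD_GFR_BAND = (31.0, 60.0)
SEVERE_CKD_GFR_BAND = (11.0, 30.0)


@dataclass(frozen=True)
class OrganSpec:
    """One perfused organ: volume (L), blood flow (L/min), composition key."""

    name: str
    volume: float
    blood_flow: float
    tissue_composition_key: str

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError(f"organ {self.name!r}: volume must be > 0, got {self.volume}")
        if not math.isnan(self.blood_flow) and self.blood_flow < 0:
            raise ValueError(f"organ {self.name!r}: blood_flow must be >= 0")


@dataclass(frozen=True)
class IndividualPhysiology:
    """A single virtual subject.

    ``clearance_weight`` is the body-weight surrogate that the drug's
    weight-specific renal clearance multiplies (actual weight for lean
    subjects, normal weight-for-height in obesity); ``clearance_scale``
    is a dimensionless renal-function multiplier (GFR relative to the
    healthy expectation for the same anthropometrics).
    """

    organs: tuple[OrganSpec, ...]
    body_weight: float  # kg
    height: float  # cm
    age: float  # years
    sex: str  # "male" | "female"
    hematocrit: float  # volume fraction
    gfr: float  # mL/min
    protein_binding_factor: float = 1.0
    gastric_emptying_time: float = 15.0  # min
    renal_blood_flow: float = 1.24  # L/min
    hepatic_arterial_blood_flow: float = 0.43  # L/min
    cardiac_output: float = 6.07  # L/min
    clearance_weight: float | None = None
    clearance_scale: float = 1.0
    disease: str = "healthy"

    def __post_init__(self) -> None:
        if not 0 < self.hematocrit < 1:
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hematocrit}")
        if self.gfr < 0:
            raise ValueError("gfr must be >= 0")
        if self.protein_binding_factor <= 0:
            raise ValueError("protein_binding_factor must be > 0")
        for name, value in (("body_weight", self.body_weight), ("height", self.height), ("age", self.age)):
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        names = [o.name for o in self.organs]
        if len(names) != len(set(names)):
            raise ValueError("organ names must be unique")
        q_sum = self.perfusion_sum
        if q_sum > self.cardiac_output * 1.05:
            raise ValueError(
                f"non-lung organ blood flows ({q_sum:.3f} L/min) exceed cardiac output "
                f"({self.cardiac_output:.3f} L/min) by more than 5%"
            )

    @property
    def perfusion_sum(self) -> float:
        """Sum of non-lung organ blood flows (L/min)."""
        return sum(
            o.blood_flow
            for o in self.organs
            if o.name != "lung" and o.name not in _BLOOD_POOLS and not math.isnan(o.blood_flow)
        )

    @property
    def total_volume(self) -> float:
        return sum(o.volume for o in self.organs)

    @property
    def blood_volume(self) -> float:
        return sum(o.volume for o in self.organs if o.name in _BLOOD_POOLS)

    @property
    def effective_clearance_weight(self) -> float:
        return self.body_weight if self.clearance_weight is None else self.clearance_weight

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)

    def with_organ(self, name: str, **changes) -> "IndividualPhysiology":
        organs = tuple(replace(o, **changes) if o.name == name else o for o in self.organs)
        return replace(self, organs=organs)

    def to_dict(self) -> dict:
        """YAML-friendly representation of the full physiology."""
        return {
            "body_weight": self.body_weight,
            "height": self.height,
            "age": self.age,
            "sex": self.sex,
            "hematocrit": self.hematocrit,
            "gfr": self.gfr,
            "protein_binding_factor": self.protein_binding_factor,
            "gastric_emptying_time": self.gastric_emptying_time,
            "renal_blood_flow": self.renal_blood_flow,
            "hepatic_arterial_blood_flow": self.hepatic_arterial_blood_flow,
            "cardiac_output": self.cardiac_output,
            "clearance_weight": self.effective_clearance_weight,
            "clearance_scale": self.clearance_scale,
            "disease": self.disease,
            "organs": {
                o.name: {
                    "volume_l": o.volume,
                    "blood_flow_l_min": None if math.isnan(o.blood_flow) else o.blood_flow,
                    "composition": o.tissue_composition_key,
                }
                for o in self.organs
            },
        }


@dataclass(frozen=True)
class PopulationDemographics:
    """Demographic envelope of one clinical study cohort."""

    n_subjects: int
    age_range: tuple[float, float]
    weight_range: tuple[float, float]
    n_females: int = 0
    disease_state: str = "healthy"

    _STATES = ("healthy", "moderate_ckd", "severe_ckd", "obese", "pediatric")

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_females > self.n_subjects:
            raise ValueError("n_females cannot exceed n_subjects")
        if self.n_females < 0:
            raise ValueError("n_females must be >= 0")
        for label, (lo, hi) in (("age_range", self.age_range), ("weight_range", self.weight_range)):
            if lo > hi or lo <= 0:
                raise ValueError(f"{label} must satisfy 0 < min <= max, got {(lo, hi)}")
        if self.disease_state not in self._STATES:
            raise ValueError(f"disease_state must be one of {self._STATES}")


@dataclass(frozen=True)
class DiseaseModifierSet:
    """Named physiology modifiers: absolute overrides and relative multipliers."""

    overrides: dict[str, float] = field(default_factory=dict)
    multipliers: dict[str, float] = field(default_factory=dict)

    _FIELDS = (
        "hematocrit",
        "protein_binding_factor",
        "gastric_emptying_time",
        "renal_blood_flow",
        "hepatic_arterial_blood_flow",
        "gfr",
    )

    def __post_init__(self) -> None:
        for source in (self.overrides, self.multipliers):
            for key, value in source.items():
                if key not in self._FIELDS and not key.startswith("organ_flow:"):
                    raise ValueError(f"unknown physiology field {key!r}")
                if value <= 0:
                    raise ValueError(f"modifier {key!r} must be positive, got {value}")

    def apply(self, phys: IndividualPhysiology) -> IndividualPhysiology:
        changes: dict[str, float] = {}
        for key, value in self.multipliers.items():
            if key.startswith("organ_flow:"):
                phys = _scale_organ_flow(phys, key.split(":", 1)[1], value)
            else:
                changes[key] = getattr(phys, key) * value
        for key, value in self.overrides.items():
            if key.startswith("organ_flow:"):
                phys = _set_organ_flow(phys, key.split(":", 1)[1], value)
            else:
                changes[key] = value
        return replace(phys, **changes)


def _set_organ_flow(phys: IndividualPhysiology, organ: str, flow: float) -> IndividualPhysiology:
    phys = phys.with_organ(organ, blood_flow=flow)
    return replace(phys, cardiac_output=phys.perfusion_sum)


def _scale_organ_flow(phys: IndividualPhysiology, organ: str, factor: float) -> IndividualPhysiology:
    return _set_organ_flow(phys, organ, phys.organ(organ).blood_flow * factor)


def du_bois_bsa(weight: float, height: float) -> float:
    """Du Bois body surface area (m^2) from weight (kg) and height (cm)."""
    if weight <= 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    if height <= 0:
        raise ValueError(f"height must be > 0, got {height}")
    return 0.007184 * weight**0.425 * height**0.725


def build_reference_adult(weight: float, height: float, age: float, sex: str = "male") -> IndividualPhysiology:
    """Construct a healthy adult from the baked-in reference organ table.

    Organ volumes are linearly rescaled so total volume equals body weight
    at unit density; organ blood flows scale with (weight/70)^0.75.
    """
    if not 20 <= weight <= 250:
        raise ValueError(f"weight out of bounds [20, 250] kg: {weight}")
    if not 120 <= height <= 220:
        raise ValueError(f"height out of bounds [120, 220] cm: {height}")
    if not 18 <= age <= 100:
        raise ValueError(f"age out of bounds [18, 100] y: {age}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")

    total_ref = sum(v for v, _, _ in _REFERENCE_ORGANS.values())
    v_scale = weight / total_ref
    q_scale = (weight / _REFERENCE_WEIGHT_KG) ** 0.75
    organs = tuple(
        OrganSpec(
            name=name,
            volume=vol * v_scale,
            blood_flow=flow if math.isnan(flow) else flow * q_scale,
            tissue_composition_key=key,
        )
        for name, (vol, flow, key) in _REFERENCE_ORGANS.items()
    )
    q_sum = sum(
        o.blood_flow
        for o in organs
        if o.name != "lung" and o.name not in _BLOOD_POOLS and not math.isnan(o.blood_flow)
    )
    return IndividualPhysiology(
        organs=organs,
        body_weight=weight,
        height=height,
        age=age,
        sex=sex,
        hematocrit=0.45 if sex == "male" else 0.40,
        gfr=HEALTHY_ADULT_GFR_ML_MIN,
        protein_binding_factor=1.0,
        gastric_emptying_time=15.0,
        renal_blood_flow=_REFERENCE_ORGANS["kidney"][1] * q_scale,
        hepatic_arterial_blood_flow=_REFERENCE_ORGANS["liver"][1] * q_scale,
        cardiac_output=q_sum,
        clearance_weight=None,
        clearance_scale=1.0,
        disease="healthy",
    )


def _require_healthy(phys: IndividualPhysiology, transform: str) -> None:
    if phys.disease != "healthy":
        raise ValueError(
            f"{transform} requires a healthy physiology; got disease={phys.disease!r} "
            "(disease transforms must not be stacked)"
        )


def apply_moderate_ckd(phys: IndividualPhysiology, gfr: float | None = None) -> IndividualPhysiology:
    """Moderate renal impairment: GET 20.625 min, PBF 0.9265, HCT 0.433.

    GFR defaults to the midpoint of the moderate band (31-60 mL/min);
    renal clearance scales with GFR relative to the healthy 120 mL/min.
    Organ blood flows are unchanged in moderate disease.
    """
    _require_healthy(phys, "apply_moderate_ckd")
    lo, hi = MODERATE_CKD_GFR_BAND
    gfr = 0.5 * (lo + hi) if gfr is None else gfr
    if not lo <= gfr <= hi:
        raise ValueError(f"moderate-CKD GFR must lie in [{lo}, {hi}] mL/min, got {gfr}")
    return replace(
        phys,
        gastric_emptying_time=20.625,
        protein_binding_factor=0.9265,
        hematocrit=0.433,
        gfr=gfr,
        clearance_scale=phys.clearance_scale * gfr / HEALTHY_ADULT_GFR_ML_MIN,
        disease="moderate_ckd",
    )


def apply_severe_ckd(phys: IndividualPhysiology, gfr: float | None = None) -> IndividualPhysiology:
    """Severe renal impairment: GET 24.375 min, HCT 0.398, PBF 0.837,
    RBF 0.17 L/min, HABF 0.16 L/min.

    The kidney and hepatic-arterial organ flows are set to the reduced
    absolute values; cardiac output is recomputed from the flow sum.
    """
    _require_healthy(phys, "apply_severe_ckd")
    lo, hi = SEVERE_CKD_GFR_BAND
    gfr = 0.5 * (lo + hi) if gfr is None else gfr
    if not lo <= gfr <= hi:
        raise ValueError(f"severe-CKD GFR must lie in [{lo}, {hi}] mL/min, got {gfr}")
    out = replace(
        phys,
        gastric_emptying_time=24.375,
        hematocrit=0.398,
        protein_binding_factor=0.837,
        renal_blood_flow=0.17,
        hepatic_arterial_blood_flow=0.16,
        gfr=gfr,
        clearance_scale=phys.clearance_scale * gfr / HEALTHY_ADULT_GFR_ML_MIN,
        disease="severe_ckd",
    )
    out = out.with_organ("kidney", blood_flow=0.17)
    out = out.with_organ("liver", blood_flow=0.16)
    return replace(out, cardiac_output=out.perfusion_sum)


def apply_obesity(phys: IndividualPhysiology) -> IndividualPhysiology:
    """Obesity: GFR = 143 mL/min per 1.73 m^2 of Du Bois BSA; HCT and plasma
    protein binding unchanged; excess weight assigned to adipose volume.

    Non-adipose organs are kept at the size expected for normal weight-
    for-height (BMI 25); the drug's weight-specific renal clearance is
    referenced to that normal weight, not total body weight.
    """
    _require_healthy(phys, "apply_obesity")
    bmi = phys.body_weight / (phys.height / 100.0) ** 2
    if bmi <= 30:
        warnings.warn(
            f"apply_obesity called with BMI {bmi:.1f} <= 30 kg/m^2; transform applied anyway",
            stacklevel=2,
        )
    normal_weight = min(phys.body_weight, 25.0 * (phys.height / 100.0) ** 2)
    shrink = normal_weight / phys.body_weight
    organs = []
    non_adipose_total = 0.0
    for o in phys.organs:
        if o.name == "adipose":
            organs.append(o)
            continue
        o = replace(o, volume=o.volume * shrink)
        non_adipose_total += o.volume
        organs.append(o)
    adipose_volume = phys.body_weight - non_adipose_total
    organs = [replace(o, volume=adipose_volume) if o.name == "adipose" else o for o in organs]
    bsa = du_bois_bsa(phys.body_weight, phys.height)
    return replace(
        phys,
        organs=tuple(organs),
        gfr=143.0 * bsa / 1.73,
        clearance_weight=normal_weight,
        disease="obese",
    )


def apply_pediatric(phys: IndividualPhysiology, age: float, weight: float) -> IndividualPhysiology:
    """Pediatric variant: volumes scale linearly with weight, the eleven
    literature organ flows (given at 70 kg-equivalent) and GFR scale with
    (weight/70)^0.75.

    The weight-specific renal clearance gains a (weight/70)^-0.25 factor so
    that absolute clearance follows 0.75-power allometry.
    """
    if not (2.0 / 12.0) <= age <= 18.0:
        raise ValueError(f"pediatric age must lie in [2 months, 18 y], got {age} y")
    if not 2.5 <= weight <= 80.0:
        raise ValueError(f"pediatric weight out of bounds [2.5, 80] kg: {weight}")
    v_scale = weight / phys.body_weight
    q_alo = (weight / _REFERENCE_WEIGHT_KG) ** 0.75
    q_rel = (weight / phys.body_weight) ** 0.75
    organs = []
    for o in phys.organs:
        flow = o.blood_flow
        if o.name in PEDIATRIC_FLOWS_L_MIN:
            flow = PEDIATRIC_FLOWS_L_MIN[o.name] * q_alo
        elif not math.isnan(flow):
            flow = flow * q_rel
        organs.append(replace(o, volume=o.volume * v_scale, blood_flow=flow))
    height = 100.0 * math.sqrt(weight / 16.5)  # BMI ~16.5 kg/m^2 proxy
    q_sum = sum(
        o.blood_flow
        for o in organs
        if o.name != "lung" and o.name not in _BLOOD_POOLS and not math.isnan(o.blood_flow)
    )
    return replace(
        phys,
        organs=tuple(organs),
        body_weight=weight,
        height=height,
        age=age,
        gfr=HEALTHY_ADULT_GFR_ML_MIN * q_alo,
        renal_blood_flow=PEDIATRIC_FLOWS_L_MIN["kidney"] * q_alo,
        hepatic_arterial_blood_flow=PEDIATRIC_FLOWS_L_MIN["liver"] * q_alo,
        cardiac_output=q_sum,
        clearance_weight=weight,
        clearance_scale=(weight / _REFERENCE_WEIGHT_KG) ** -0.25,
        disease="pediatric",
    )
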