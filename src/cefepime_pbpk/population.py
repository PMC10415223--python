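"""Seeded virtual populations matched to study demographics, population
simulation, and percentile-band summaries for visual predictive checks."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import physiology as phys_mod
from .distribution import (
    DrugParameters,
    compute_kp_set,
    fu_adjusted,
    load_tissue_compositions,
)
from .engine import ConcentrationTimeProfile, DoseRegimen, assemble_model, simulate
from .physiology import IndividualPhysiology, PopulationDemographics

__all__ = [
    "VirtualPopulation",
    "PercentileBands",
    "sample_population",
    "simulate_population",
    "summarize_bands",
]

# BMI envelopes used to back-calculate height from sampled weight; study
# tables report weight ranges only.
_BMI_RANGES = {
    "healthy": (20.0, 27.0),
    "moderate_ckd": (20.0, 27.0),
    "severe_ckd": (20.0, 27.0),
    "obese": (31.0, 45.0),
    "pediatric": (14.0, 19.0),
}


@dataclass(frozen=True)
class VirtualPopulation:
    subjects: tuple[IndividualPhysiology, ...]
    seed: int
    demographics: PopulationDemographics

    def __post_init__(self) -> None:
        if len(self.subjects) != self.demographics.n_subjects:
            raise ValueError("subject count does not match demographics")


@dataclass(frozen=True)
class PercentileBands:
    """Pointwise population summary: mean, 5th/95th percentile, min, max."""

    times: np.ndarray
    mean: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        eps = 1e-12
        if not (
            np.all(self.minimum <= self.p5 + eps)
            and np.all(self.p5 <= self.p95 + eps)
            and np.all(self.p95 <= self.maximum + eps)
        ):
            raise ValueError("band ordering violated: need min <= p5 <= p95 <= max")
        if not (np.all(self.mean >= self.minimum - eps) and np.all(self.mean <= self.maximum + eps)):
            raise ValueError("mean must lie within [min, max]")


def sample_population(demo: PopulationDemographics, seed: int) -> VirtualPopulation:
    """Draw a reproducible virtual cohort.

    Ages and weights are uniform over the reported ranges; height is
    back-calculated from weight and a cohort-appropriate BMI draw; sex
    assignment matches the reported number of females.
    """
    rng = np.random.default_rng(seed)
    n = demo.n_subjects
    ages = rng.uniform(*demo.age_range, size=n)
    weights = rng.uniform(*demo.weight_range, size=n)
    bmis = rng.uniform(*_BMI_RANGES[demo.disease_state], size=n)
    sexes = np.array(["female"] * demo.n_females + ["male"] * (n - demo.n_females))
    rng.shuffle(sexes)

    subjects = []
    for age, weight, bmi, sex in zip(ages, weights, bmis, sexes):
        if demo.disease_state == "pediatric":
            ref = phys_mod.build_reference_adult(70.0, 170.0, 30.0, sex)
            subjects.append(phys_mod.apply_pediatric(ref, age=float(age), weight=float(weight)))
            continue
        height = float(np.clip(100.0 * np.sqrt(weight / bmi), 120.0, 220.0))
        base = phys_mod.build_reference_adult(float(weight), height, float(age), sex)
        if demo.disease_state == "moderate_ckd":
            base = phys_mod.apply_moderate_ckd(base)
        elif demo.disease_state == "severe_ckd":
            base = phys_mod.apply_severe_ckd(base)
        elif demo.disease_state == "obese":
            base = phys_mod.apply_obesity(base)
        subjects.append(base)
    return VirtualPopulation(subjects=tuple(subjects), seed=seed, demographics=demo)


def simulate_population(
    pop: VirtualPopulation,
    drug: DrugParameters,
    regimen: DoseRegimen,
    output_times: np.ndarray,
    compositions: dict | None = None,
) -> list[ConcentrationTimeProfile]:
    """One venous-plasma profile per subject.

    Each subject's partition coefficients are recomputed from their own
    disease-adjusted unbound fraction.
    """
    if not pop.subjects:
        raise ValueError("population is empty")
    if compositions is None:
        compositions = load_tissue_compositions()
    profiles = []
    for i, subject in enumerate(pop.subjects):
        try:
            fu = fu_adjusted(drug, subject)
            kps = compute_kp_set(drug, compositions, fu, phys=subject)
            model = assemble_model(subject, drug, kps)
            profile = simulate(model, regimen, output_times)
        except Exception as err:
            raise RuntimeError(f"simulation failed for subject index {i}") from err
        profile.metadata["subject_index"] = i
        profiles.append(profile)
    return profiles


def summarize_bands(profiles: list[ConcentrationTimeProfile]) -> PercentileBands:
    """Pointwise mean, empirical 5th/95th percentile (linear interpolation),
    minimum and maximum across profiles sharing one time grid."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to summarize")
    times = profiles[0].times
    for p in profiles[1:]:
        if p.times.shape != times.shape or not np.allclose(p.times, times):
            raise ValueError("profiles are not on a common time grid")
    matrix = np.vstack([p.concentrations for p in profiles])
    return PercentileBands(
        times=times,
        mean=matrix.mean(axis=0),
        p5=np.percentile(matrix, 5, axis=0, method="linear"),
        p95=np.percentile(matrix, 95, axis=0, method="linear"),
        minimum=matrix.min(axis=0),
        maximum=matrix.max(axis=0),
    )
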