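"""Cefepime parameters, ionization, disease-adjusted plasma binding and
tissue:plasma partition coefficients.

Partition coefficients follow the Rodgers-Rowland tissue-composition
framework: the unbound tissue:plasma ratio (Kpu) is assembled from water
fractions, ionization at tissue vs plasma pH, neutral-lipid partitioning
of the un-ionized species, and extravascular-albumin binding; the
plasma-referenced coefficient is Kp = fu * Kpu.

Cefepime carries a permanently cationic quaternary ammonium and a
carboxylate (pKa 4.06), so at physiological pH essentially all drug is
the net-neutral zwitterion on both sides of the membrane.  The
zwitterion branch therefore uses the zwitterionic species as permeant
reference (intracellular-to-extracellular unbound ratio ~1) and omits
neutral-lipid partitioning, which for charge-separated betaine-like
species is orders of magnitude below the neutral-species log P.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .physiology import IndividualPhysiology

__all__ = [
    "DrugParameters",
    "TissueComposition",
    "cefepime_defaults",
    "load_tissue_compositions",
    "ionized_fraction",
    "fu_adjusted",
    "compute_kp_set",
    "blood_to_plasma_ratio",
    "vss_per_kg",
    "PLASMA_PH",
]

PLASMA_PH = 7.4
# plasma neutral lipid / neutral phospholipid volume fractions
_PLASMA_F_NL = 0.0023
_PLASMA_F_NP = 0.0013

_IONIZATION_CLASSES = ("neutral", "acid", "base", "zwitterion")


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemistry, plasma binding and renal clearance of the compound."""

    molecular_weight: float  # g/mol
    log_p: float
    pka_1: float  # higher pKa (for cefepime: 13.2)
    pka_2: float  # lower pKa (for cefepime: 4.06, carboxylic acid)
    ionization_class: str
    fu_plasma: float  # fraction unbound in healthy plasma
    renal_clearance_ml_min_kg: float  # specific renal clearance, mL/min/kg
    erythrocyte_partition: float = 0.0  # Kp of red cells vs plasma

    def __post_init__(self) -> None:
        if not 0 < self.fu_plasma <= 1:
            raise ValueError(f"fu_plasma must be in (0, 1], got {self.fu_plasma}")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        if self.renal_clearance_ml_min_kg < 0:
            raise ValueError("renal clearance must be >= 0")
        if self.ionization_class not in _IONIZATION_CLASSES:
            raise ValueError(f"ionization_class must be one of {_IONIZATION_CLASSES}")


@dataclass(frozen=True)
class TissueComposition:
    """Fractional composition of one tissue."""

    f_ew: float  # extracellular water
    f_iw: float  # intracellular water
    f_nl: float  # neutral lipid
    f_np: float  # neutral phospholipid
    ra_albumin: float  # tissue:plasma albumin ratio
    ph: float = 7.0

    def __post_init__(self) -> None:
        for name in ("f_ew", "f_iw", "f_nl", "f_np"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.f_ew + self.f_iw + self.f_nl + self.f_np > 1.0 + 1e-9:
            raise ValueError("water plus lipid fractions exceed 1")


def cefepime_defaults() -> DrugParameters:
    """Cefepime hydrochloride parameter set used throughout the package."""
    return DrugParameters(
        molecular_weight=517.0,
        log_p=0.6914,
        pka_1=13.2,
        pka_2=4.06,
        ionization_class="zwitterion",
        fu_plasma=0.55,
        renal_clearance_ml_min_kg=2.1,
        erythrocyte_partition=0.0,
    )


def load_tissue_compositions() -> dict[str, TissueComposition]:
    """Read the packaged tissue-composition table keyed by composition name."""
    with resources.files("cefepime_pbpk").joinpath("data/tissue_composition.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    return {
        row.tissue: TissueComposition(
            f_ew=row.f_ew, f_iw=row.f_iw, f_nl=row.f_nl, f_np=row.f_np,
            ra_albumin=row.ra_albumin, ph=row.ph,
        )
        for row in table.itertuples()
    }


def ionized_fraction(pka: float, ph: float, kind: str) -> float:
    """Henderson-Hasselbalch ionized fraction of a monoprotic group."""
    if not 0 < ph < 14:
        raise ValueError(f"ph must lie in (0, 14), got {ph}")
    if kind == "acid":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    if kind == "base":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    raise ValueError(f"kind must be 'acid' or 'base', got {kind!r}")


def fu_adjusted(drug: DrugParameters, phys: IndividualPhysiology) -> float:
    """Unbound fraction after scaling binding-protein concentration by PBF.

    fu' = 1 / (1 + PBF * (1 - fu) / fu); PBF = 1 is the identity and a
    reduced binding-protein pool (PBF < 1) raises the unbound fraction.
    """
    fu = drug.fu_plasma
    pbf = phys.protein_binding_factor
    return 1.0 / (1.0 + pbf * (1.0 - fu) / fu)


def _ionization_terms(drug: DrugParameters, ph: float) -> float:
    """Sum of ionized-species terms relative to the permeant reference species."""
    cls = drug.ionization_class
    if cls == "neutral":
        return 0.0
    if cls == "acid":
        return 10.0 ** (ph - drug.pka_1)
    if cls == "base":
        return 10.0 ** (drug.pka_1 - ph)
    # zwitterion: cation below the low pKa, anion above the high pKa,
    # permeant reference species is the net-neutral zwitterion
    return 10.0 ** (drug.pka_2 - ph) + 10.0 ** (ph - drug.pka_1)


def _kpu(drug: DrugParameters, comp: TissueComposition, fu: float) -> float:
    p = 10.0**drug.log_p
    x = 1.0 + _ionization_terms(drug, comp.ph)
    y = 1.0 + _ionization_terms(drug, PLASMA_PH)
    if drug.ionization_class == "zwitterion":
        # permanent charge separation: no neutral-lipid partitioning,
        # in plasma or in tissue
        lipid_tissue = 0.0
        lipid_plasma = 0.0
    else:
        lipid_tissue = (p * comp.f_nl + (0.3 * p + 0.7) * comp.f_np) / y
        lipid_plasma = p * _PLASMA_F_NL + (0.3 * p + 0.7) * _PLASMA_F_NP
    protein = comp.ra_albumin * max(0.0, 1.0 / fu - 1.0 - lipid_plasma)
    return comp.f_ew + (x / y) * comp.f_iw + lipid_tissue + protein


def compute_kp_set(
    drug: DrugParameters,
    compositions: dict[str, TissueComposition],
    fu: float,
    phys: IndividualPhysiology | None = None,
) -> dict[str, float]:
    """Tissue:plasma partition coefficients for every perfused organ.

    When ``phys`` is given, Kp values are keyed by organ name using each
    organ's composition key; otherwise they are keyed by composition name.
    """
    if not 0 < fu <= 1:
        raise ValueError(f"fu must lie in (0, 1], got {fu}")
    if phys is None:
        return {name: fu * _kpu(drug, comp, fu) for name, comp in compositions.items()}
    kps: dict[str, float] = {}
    for organ in phys.organs:
        if organ.tissue_composition_key == "blood":
            continue
        comp = compositions.get(organ.tissue_composition_key)
        if comp is None:
            raise KeyError(
                f"no tissue composition {organ.tissue_composition_key!r} for organ {organ.name!r}"
            )
        kps[organ.name] = fu * _kpu(drug, comp, fu)
    return kps


def blood_to_plasma_ratio(drug: DrugParameters, hematocrit: float) -> float:
    """Blood:plasma concentration ratio; cefepime is confined to plasma
    (no erythrocyte partitioning), so B:P = 1 - HCT."""
    return (1.0 - hematocrit) + hematocrit * drug.erythrocyte_partition


def vss_per_kg(phys: IndividualPhysiology, kps: dict[str, float]) -> float:
    """Plasma-referenced steady-state distribution volume, L/kg."""
    tissue = sum(
        organ.volume * kps[organ.name]
        for organ in phys.organs
        if organ.name in kps
    )
    plasma = phys.blood_volume * (1.0 - phys.hematocrit)
    return (tissue + plasma) / phys.body_weight
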