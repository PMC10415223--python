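"""Whole-body ODE system: perfusion-limited organs, venous/arterial pools,
lung in series with cardiac output, IV-infusion input and renal elimination.

Unit conventions, fixed package-wide: time h, amounts mg, volumes L,
concentrations ug/mL (= mg/L).  Organ blood flows are carried on the
physiology in L/min and converted to L/h once at model assembly.

The state vector holds drug amount (mg) per compartment in the order
[arterial blood, venous blood, lung, tissue_1..tissue_n] plus one
trailing state accumulating the eliminated amount.  Splanchnic organs
drain through the portal vein into the liver; every other tissue returns
to the venous pool directly.  Renal elimination removes drug from the
kidney compartment at CL_plasma times the arterial (kidney-inflow)
plasma concentration, which for a linear model makes dose/AUC equal to
CL_plasma identically.  The observation compartment is venous plasma,
converted from blood via the blood:plasma ratio.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .distribution import DrugParameters, blood_to_plasma_ratio
from .physiology import SPLANCHNIC_ORGANS, IndividualPhysiology

__all__ = [
    "DoseRegimen",
    "ODEModel",
    "ConcentrationTimeProfile",
    "SimulationResult",
    "assemble_model",
    "simulate",
    "mass_balance",
    "default_output_times",
    "write_profile",
    "read_profile",
]

RTOL = 1e-8
ATOL = 1e-10  # mg


@dataclass(frozen=True)
class DoseRegimen:
    """An IV-infusion regimen (single dose by default)."""

    dose_mg: float | None = None
    dose_mg_per_kg: float | None = None
    infusion_duration_min: float = 30.0
    start_time_h: float = 0.0
    n_doses: int = 1
    interdose_interval_h: float = 0.0

    def __post_init__(self) -> None:
        if (self.dose_mg is None) == (self.dose_mg_per_kg is None):
            raise ValueError("specify exactly one of dose_mg or dose_mg_per_kg")
        amount = self.dose_mg if self.dose_mg is not None else self.dose_mg_per_kg
        if amount < 0:
            raise ValueError("dose must be >= 0")
        if not self.infusion_duration_min > 0:
            raise ValueError("infusion_duration_min must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.n_doses > 1 and self.interdose_interval_h <= self.infusion_duration_min / 60.0:
            raise ValueError("interdose_interval_h must exceed the infusion duration")

    def resolve_dose(self, body_weight: float) -> float:
        """Absolute dose in mg for a subject of the given weight."""
        if self.dose_mg is not None:
            return self.dose_mg
        return self.dose_mg_per_kg * body_weight

    def infusion_windows(self, body_weight: float) -> list[tuple[float, float, float]]:
        """(start_h, end_h, rate mg/h) for each administered dose."""
        dose = self.resolve_dose(body_weight)
        dur_h = self.infusion_duration_min / 60.0
        windows = []
        for i in range(self.n_doses):
            t0 = self.start_time_h + i * self.interdose_interval_h
            windows.append((t0, t0 + dur_h, dose / dur_h))
        return windows


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """Venous-plasma concentration series (times h, concentrations ug/mL)."""

    times: np.ndarray
    concentrations: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be 1-d arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(c)):
            raise ValueError("concentrations must be finite")
        if np.any(c < -1e-9):
            raise ValueError("negative concentrations")
        object.__setattr__(self, "concentrations", np.clip(c, 0.0, None))

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ODEModel:
    """Assembled linear disposition model for one individual."""

    phys: IndividualPhysiology
    drug: DrugParameters
    kps: dict[str, float]
    tissue_names: tuple[str, ...]
    tissue_volumes: np.ndarray  # L
    tissue_flows: np.ndarray  # L/h blood
    tissue_kp: np.ndarray
    v_art: float
    v_ven: float
    v_lung: float
    kp_lung: float
    q_co: float  # L/h blood
    bp: float  # blood:plasma ratio
    cl_plasma: float  # L/h
    splanchnic_idx: tuple[int, ...]
    liver_idx: int
    kidney_idx: int | None

    @property
    def n_states(self) -> int:
        # arterial, venous, lung, tissues, eliminated
        return 3 + len(self.tissue_names) + 1


def clearance_plasma_l_h(phys: IndividualPhysiology, drug: DrugParameters) -> float:
    """Renal plasma clearance in L/h for one individual."""
    return (
        drug.renal_clearance_ml_min_kg
        * 0.06
        * phys.effective_clearance_weight
        * phys.clearance_scale
    )


def assemble_model(
    phys: IndividualPhysiology,
    drug: DrugParameters,
    kps: dict[str, float],
) -> ODEModel:
    """Wire organs, flows and partition coefficients into the ODE layout."""
    tissue_names = tuple(
        o.name for o in phys.organs if o.name not in ("lung", "arterial_blood", "venous_blood")
    )
    missing = [name for name in tissue_names if name not in kps]
    if "lung" not in kps:
        missing.append("lung")
    if missing:
        raise ValueError(f"partition coefficients missing for organs: {missing}")
    for name, kp in kps.items():
        if not (np.isfinite(kp) and kp > 0):
            raise ValueError(f"Kp for {name!r} must be finite and positive, got {kp}")

    volumes = np.array([phys.organ(n).volume for n in tissue_names])
    flows = np.array([phys.organ(n).blood_flow * 60.0 for n in tissue_names])  # L/h
    kp = np.array([kps[n] for n in tissue_names])
    splanchnic_idx = tuple(i for i, n in enumerate(tissue_names) if n in SPLANCHNIC_ORGANS)
    liver_idx = tissue_names.index("liver") if "liver" in tissue_names else -1
    if liver_idx < 0 and splanchnic_idx:
        raise ValueError("splanchnic organs present but no liver to drain into")
    kidney_idx = tissue_names.index("kidney") if "kidney" in tissue_names else None

    return ODEModel(
        phys=phys,
        drug=drug,
        kps=dict(kps),
        tissue_names=tissue_names,
        tissue_volumes=volumes,
        tissue_flows=flows,
        tissue_kp=kp,
        v_art=phys.organ("arterial_blood").volume,
        v_ven=phys.organ("venous_blood").volume,
        v_lung=phys.organ("lung").volume,
        kp_lung=kps["lung"],
        q_co=phys.perfusion_sum * 60.0,
        bp=blood_to_plasma_ratio(drug, phys.hematocrit),
        cl_plasma=clearance_plasma_l_h(phys, drug),
        splanchnic_idx=splanchnic_idx,
        liver_idx=liver_idx,
        kidney_idx=kidney_idx,
    )


def _system_matrix(model: ODEModel) -> np.ndarray:
    """Constant coefficient matrix A with x' = A x + u(t) e_venous."""
    n_t = len(model.tissue_names)
    n = 3 + n_t + 1
    a = np.zeros((n, n))
    ART, VEN, LUNG = 0, 1, 2
    bp = model.bp
    q_co = model.q_co

    # lung: in series with total venous return
    a[LUNG, VEN] += q_co / model.v_ven
    a[LUNG, LUNG] -= q_co * bp / (model.kp_lung * model.v_lung)
    # arterial pool fed by lung outflow, drained by all organ flows
    a[ART, LUNG] += q_co * bp / (model.kp_lung * model.v_lung)
    a[ART, ART] -= q_co / model.v_art

    portal_out = 0.0
    for i, name in enumerate(model.tissue_names):
        row = 3 + i
        q = model.tissue_flows[i]
        k_out = q * bp / (model.tissue_kp[i] * model.tissue_volumes[i])
        a[row, ART] += q / model.v_art
        a[row, row] -= k_out
        if i in model.splanchnic_idx:
            a[3 + model.liver_idx, row] += k_out  # portal vein into liver
            portal_out += q
        elif i == model.liver_idx:
            pass  # liver outflow handled below
        else:
            a[VEN, row] += k_out
    if model.liver_idx >= 0:
        li = 3 + model.liver_idx
        q_liver_out = model.tissue_flows[model.liver_idx] + portal_out
        k_li = q_liver_out * bp / (model.tissue_kp[model.liver_idx] * model.tissue_volumes[model.liver_idx])
        # liver outflow replaces the generic term: subtract hepatic-artery-only
        # outflow already placed on the diagonal, then add the full one
        q_ha = model.tissue_flows[model.liver_idx]
        a[li, li] += q_ha * bp / (model.tissue_kp[model.liver_idx] * model.tissue_volumes[model.liver_idx])
        a[li, li] -= k_li
        a[VEN, li] += k_li
    a[VEN, VEN] -= q_co / model.v_ven

    # renal elimination driven by arterial (kidney-inflow) plasma concentration;
    # removed from the kidney compartment (venous pool if the layout has none)
    if model.cl_plasma > 0:
        sink = 3 + model.kidney_idx if model.kidney_idx is not None else VEN
        a[sink, ART] -= model.cl_plasma / (bp * model.v_art)
        a[n - 1, ART] += model.cl_plasma / (bp * model.v_art)
    return a


@dataclass(frozen=True)
class SimulationResult:
    """Profile plus the full state trajectory needed for mass balance."""

    profile: ConcentrationTimeProfile
    states: np.ndarray  # (n_states, n_times)
    infused: np.ndarray  # cumulative infused amount at each output time


def default_output_times(horizon_h: float = 12.0, dt_h: float = 0.05) -> np.ndarray:
    return np.round(np.arange(0.0, horizon_h + dt_h / 2, dt_h), 10)


def simulate(
    model: ODEModel,
    regimen: DoseRegimen,
    output_times: np.ndarray,
    full_output: bool = False,
) -> ConcentrationTimeProfile | SimulationResult:
    """Integrate the model across infusion on/off segments.

    The integrator is restarted at every infusion boundary so the input
    discontinuities never cross a solver step.
    """
    times = np.asarray(output_times, dtype=float)
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("output_times must be strictly increasing with >= 2 points")
    if times[0] < 0:
        raise ValueError("output_times must start at or after 0")

    a = _system_matrix(model)
    windows = regimen.infusion_windows(model.phys.body_weight)
    VEN = 1

    breakpoints = sorted({0.0, times[-1], *[w[0] for w in windows], *[w[1] for w in windows]})
    breakpoints = [b for b in breakpoints if 0.0 <= b <= times[-1]]
    if breakpoints[-1] < times[-1]:
        breakpoints.append(times[-1])

    def rate_at(t0: float, t1: float) -> float:
        mid = 0.5 * (t0 + t1)
        for w0, w1, r in windows:
            if w0 <= mid < w1:
                return r
        return 0.0

    x = np.zeros(a.shape[0])
    out = np.empty((a.shape[0], times.size))
    filled = np.zeros(times.size, dtype=bool)
    if times[0] == 0.0:
        out[:, 0] = x
        filled[0] = True

    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        if t1 <= t0:
            continue
        r = rate_at(t0, t1)
        u = np.zeros(a.shape[0])
        u[VEN] = r

        def rhs(t, y, _a=a, _u=u):
            return _a @ y + _u

        mask = (times > t0 + 1e-12) & (times <= t1 + 1e-12)
        t_eval = times[mask]
        sol = solve_ivp(
            rhs,
            (t0, t1),
            x,
            method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=RTOL,
            atol=ATOL,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed in segment [{t0}, {t1}] h: {sol.message}")
        if t_eval.size:
            out[:, mask] = sol.y
            filled[mask] = True
        x = sol.y[:, -1] if sol.y.shape[1] else x
        # re-integrate to segment end if t_eval did not include it
        if t_eval.size == 0 or not math.isclose(t_eval[-1], t1, rel_tol=0, abs_tol=1e-9):
            sol_end = solve_ivp(rhs, (t_eval[-1] if t_eval.size else t0, t1), x,
                                method="LSODA", rtol=RTOL, atol=ATOL)
            if not sol_end.success:
                raise RuntimeError(f"ODE integration failed reaching {t1} h: {sol_end.message}")
            x = sol_end.y[:, -1]

    if not np.all(filled):
        raise RuntimeError("internal error: output grid not fully covered")

    conc = out[VEN] / model.v_ven / model.bp  # venous plasma, mg/L == ug/mL
    conc = np.where(np.abs(conc) < 1e-12, 0.0, conc)
    profile = ConcentrationTimeProfile(
        times=times,
        concentrations=conc,
        metadata={
            "dose_mg": regimen.resolve_dose(model.phys.body_weight),
            "infusion_duration_min": regimen.infusion_duration_min,
            "body_weight_kg": model.phys.body_weight,
            "disease": model.phys.disease,
            "cl_plasma_l_h": model.cl_plasma,
        },
    )
    if not full_output:
        return profile
    infused = np.zeros(times.size)
    for w0, w1, r in windows:
        infused += r * np.clip(np.minimum(times, w1) - w0, 0.0, None)
    return SimulationResult(profile=profile, states=out, infused=infused)


def mass_balance(model: ODEModel, result: SimulationResult) -> float:
    """|infused - (in body + eliminated)| / infused at the final time."""
    infused = result.infused[-1]
    if infused == 0:
        return 0.0
    in_body = result.states[:-1, -1].sum()
    eliminated = result.states[-1, -1]
    return abs(infused - (in_body + eliminated)) / infused


# -- profile text format -----------------------------------------------------

def write_profile(profile: ConcentrationTimeProfile, path) -> None:
    """Two-column tab-delimited text with '#'-comment metadata header."""
    buf = io.StringIO()
    for key, value in profile.metadata.items():
        buf.write(f"# {key}: {value}\n")
    buf.write("time_h\tconc_ug_ml\n")
    for t, c in zip(profile.times, profile.concentrations):
        buf.write(f"{t:.6g}\t{c:.8g}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_profile(path) -> ConcentrationTimeProfile:
    metadata: dict = {}
    times: list[float] = []
    concs: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = _coerce(value.strip())
                continue
            first = line.split("\t")[0]
            try:
                float(first)
            except ValueError:
                continue  # column header
            t_str, c_str = line.split("\t")[:2]
            times.append(float(t_str))
            concs.append(float(c_str))
    return ConcentrationTimeProfile(np.array(times), np.array(concs), metadata)


def _coerce(text: str):
    try:
        value = float(text)
    except ValueError:
        return text
    return value
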