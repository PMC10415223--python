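"""Non-compartmental analysis of concentration-time profiles.

Produces the parameters used for model qualification: Cmax/tmax, AUC by
linear-up/log-down (or pure linear) trapezoids, terminal slope lambda_z
by best-adjusted-R^2 log-linear regression over candidate tails, AUC
extrapolated to infinity, half-life and clearance.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .engine import ConcentrationTimeProfile

__all__ = [
    "PKParameters",
    "LambdaZFit",
    "cmax_tmax",
    "auc_trapezoidal",
    "terminal_slope",
    "auc_to_infinity",
    "clearance",
    "nca_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PKParameters:
    """NCA outputs for one profile."""

    cmax: float  # ug/mL
    tmax: float  # h
    auc_0_t: float  # ug/mL * h
    auc_0_inf: float  # ug/mL * h
    lambda_z: float  # 1/h
    t_half: float  # h
    cl: float  # L/h (dose in mg)
    extrapolated_fraction: float  # percent

    def __post_init__(self) -> None:
        if not self.auc_0_inf >= self.auc_0_t > 0:
            raise ValueError("require auc_0_inf >= auc_0_t > 0")
        if not 0 <= self.extrapolated_fraction < 100:
            raise ValueError("extrapolated_fraction must lie in [0, 100)")


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression diagnostics."""

    lambda_z: float  # 1/h
    intercept_log: float  # ln-intercept
    n_points: int
    r_squared: float
    adjusted_r_squared: float
    t_first: float
    t_last: float


def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Maximum observed concentration and its time; earliest time on ties."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    idx = int(np.argmax(profile.concentrations))  # argmax takes the first maximum
    return float(profile.concentrations[idx]), float(profile.times[idx])


def auc_trapezoidal(profile: ConcentrationTimeProfile, method: str = "linear-up/log-down") -> float:
    """AUC from the first to the last sampling time.

    'linear-up/log-down' uses the log trapezoid on strictly decreasing
    segments with positive endpoints, the linear trapezoid otherwise.
    """
    if method not in ("linear-up/log-down", "linear"):
        raise ValueError(f"unknown AUC method {method!r}")
    t = profile.times
    c = profile.concentrations
    if t.size < 2:
        raise ValueError("need at least 2 points for AUC")
    total = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if method == "linear-up/log-down" and c1 < c0:
            if c0 > 0 and c1 > 0:
                total += dt * (c0 - c1) / math.log(c0 / c1)
                continue
            log.debug("nonpositive concentration in decreasing segment at t=%g; linear trapezoid", t[i])
        total += dt * 0.5 * (c0 + c1)
    return float(total)


def terminal_slope(profile: ConcentrationTimeProfile, min_points: int = 3) -> LambdaZFit:
    """Fit lambda_z over the post-peak tail with the best adjusted R^2.

    Candidate point sets are the last k post-peak points for
    k = min_points .. all; concentrations must be positive and the fitted
    slope negative, otherwise the candidate is discarded.
    """
    _, tmax = cmax_tmax(profile)
    mask = (profile.times > tmax) & (profile.concentrations > 0)
    t = profile.times[mask]
    c = profile.concentrations[mask]
    if t.size < min_points:
        raise ValueError("terminal phase not identifiable: fewer than "
                         f"{min_points} positive post-peak points")
    log_c = np.log(c)
    best: LambdaZFit | None = None
    for k in range(min_points, t.size + 1):
        tt = t[-k:]
        yy = log_c[-k:]
        slope, intercept = np.polyfit(tt, yy, 1)
        if slope >= 0:
            continue
        resid = yy - (slope * tt + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        if best is None or adj > best.adjusted_r_squared + 1e-12:
            best = LambdaZFit(
                lambda_z=float(-slope),
                intercept_log=float(intercept),
                n_points=k,
                r_squared=r2,
                adjusted_r_squared=adj,
                t_first=float(tt[0]),
                t_last=float(tt[-1]),
            )
    if best is None:
        raise ValueError("terminal phase not identifiable: no decreasing tail")
    return best


def auc_to_infinity(
    profile: ConcentrationTimeProfile,
    method: str = "linear-up/log-down",
    min_points: int = 3,
) -> tuple[float, float, LambdaZFit]:
    """AUC0-inf = AUC0-t + C_last/lambda_z; also returns the extrapolated
    percentage and the terminal fit."""
    fit = terminal_slope(profile, min_points=min_points)
    auc_t = auc_trapezoidal(profile, method=method)
    c_last = float(profile.concentrations[profile.concentrations > 0][-1])
    tail = c_last / fit.lambda_z
    auc_inf = auc_t + tail
    extrap = 100.0 * tail / auc_inf
    if extrap >= 20.0:
        log.warning("extrapolated AUC fraction %.1f%% >= 20%%", extrap)
    return auc_inf, extrap, fit


def clearance(dose_mg: float, auc_0_inf: float) -> float:
    """CL = dose / AUC0-inf; mg per (ug/mL*h) is numerically L/h."""
    if auc_0_inf <= 0:
        raise ValueError("auc_0_inf must be > 0")
    return dose_mg / auc_0_inf


def nca_summary(
    profile: ConcentrationTimeProfile,
    dose_mg: float | None = None,
    method: str = "linear-up/log-down",
    per_kg: bool = False,
    body_weight: float | None = None,
) -> PKParameters:
    """Full NCA for one profile; ``per_kg`` reports CL in L/h/kg."""
    cmax, tmax = cmax_tmax(profile)
    auc_inf, extrap, fit = auc_to_infinity(profile, method=method)
    auc_t = auc_trapezoidal(profile, method=method)
    if dose_mg is None:
        dose_mg = float(profile.metadata.get("dose_mg", 0.0))
    cl = clearance(dose_mg, auc_inf) if dose_mg else 0.0
    if per_kg:
        if body_weight is None:
            body_weight = float(profile.metadata.get("body_weight_kg", 0.0))
        if not body_weight:
            raise ValueError("per-kg clearance requested without a body weight")
        cl = cl / body_weight
    return PKParameters(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        lambda_z=fit.lambda_z,
        t_half=math.log(2.0) / fit.lambda_z,
        cl=cl,
        extrapolated_fraction=extrap,
    )
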