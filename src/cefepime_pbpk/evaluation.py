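"""Model-qualification statistics: observed/predicted fold ratios, average
fold error (AFE, the geometric mean of fold ratios), the two-fold
acceptance criterion, and grouped report generation over the packaged
observed/predicted PK parameter tables."""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationRecord",
    "EvaluationSummary",
    "fold_ratio",
    "afe",
    "mean_ratio",
    "twofold_flag",
    "build_report",
    "load_fixture",
    "load_all_fixtures",
    "paper_checks",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("pk_healthy", "pk_pediatric", "pk_ckd", "pk_obese")


@dataclass(frozen=True)
class EvaluationRecord:
    """One observed/predicted pair for one PK parameter in one study."""

    study: str
    population: str
    parameter: str  # cmax | auc_0_inf | cl
    unit: str
    dose: str
    observed: float
    predicted: float
    anomaly_flag: str = ""

    def __post_init__(self) -> None:
        if self.observed <= 0 or self.predicted <= 0:
            raise ValueError("observed and predicted values must be positive")

    @property
    def ratio(self) -> float:
        return fold_ratio(self.observed, self.predicted)


@dataclass(frozen=True)
class EvaluationSummary:
    """Grouped summary for one parameter within one population group."""

    population: str
    parameter: str
    n: int
    mean_ratio: float
    ci95: tuple[float, float] | None
    afe: float
    n_within_twofold: int
    mean_observed: float
    mean_predicted: float

    def __post_init__(self) -> None:
        if self.afe <= 0:
            raise ValueError("afe must be positive")
        if self.n_within_twofold > self.n:
            raise ValueError("n_within_twofold cannot exceed n")


def fold_ratio(observed: float, predicted: float) -> float:
    """Observed-to-predicted ratio R, full precision."""
    if observed <= 0 or predicted <= 0:
        raise ValueError("fold_ratio requires positive observed and predicted values")
    return observed / predicted


def afe(ratios: Sequence[float]) -> float:
    """Average fold error: 10 ** mean(log10 ratio), the geometric mean."""
    ratios = np.asarray(list(ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError("afe requires at least one ratio")
    if np.any(ratios <= 0):
        raise ValueError("all ratios must be positive")
    return float(10.0 ** np.mean(np.log10(ratios)))


def mean_ratio(ratios: Sequence[float]) -> tuple[float, tuple[float, float] | None]:
    """Arithmetic mean of fold ratios with a normal-approximation 95% CI
    (mean +/- 1.96 * sd / sqrt(N)); no CI for a single ratio."""
    ratios = np.asarray(list(ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError("mean_ratio requires at least one ratio")
    mean = float(ratios.mean())
    if ratios.size < 2:
        return mean, None
    half = 1.96 * float(ratios.std(ddof=1)) / math.sqrt(ratios.size)
    return mean, (mean - half, mean + half)


def twofold_flag(ratio: float) -> bool:
    """True iff the ratio lies in the inclusive two-fold band [0.5, 2.0]."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return 0.5 <= ratio <= 2.0


def build_report(records: Iterable[EvaluationRecord]) -> list[EvaluationSummary]:
    """Summaries per (population, parameter), sorted deterministically.

    Column means of the observed and predicted values are emitted
    alongside ratio statistics. Mixed units within a group are an error.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to report")
    groups: dict[tuple[str, str], list[EvaluationRecord]] = {}
    for rec in records:
        groups.setdefault((rec.population, rec.parameter), []).append(rec)
    summaries = []
    for (population, parameter), group in sorted(groups.items()):
        units = {r.unit for r in group}
        if len(units) > 1:
            raise ValueError(
                f"mixed units {sorted(units)} for parameter {parameter!r} in {population!r}"
            )
        ratios = [r.ratio for r in group]
        mean, ci = mean_ratio(ratios)
        summaries.append(
            EvaluationSummary(
                population=population,
                parameter=parameter,
                n=len(group),
                mean_ratio=mean,
                ci95=ci,
                afe=afe(ratios),
                n_within_twofold=sum(twofold_flag(r) for r in ratios),
                mean_observed=float(np.mean([r.observed for r in group])),
                mean_predicted=float(np.mean([r.predicted for r in group])),
            )
        )
    return summaries


def report_frame(summaries: Sequence[EvaluationSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "population": s.population,
                "parameter": s.parameter,
                "n": s.n,
                "mean_ratio": s.mean_ratio,
                "ci95_low": None if s.ci95 is None else s.ci95[0],
                "ci95_high": None if s.ci95 is None else s.ci95[1],
                "afe": s.afe,
                "n_within_twofold": s.n_within_twofold,
                "mean_observed": s.mean_observed,
                "mean_predicted": s.mean_predicted,
            }
        )
    return pd.DataFrame(rows)


def _records_from_frame(table: pd.DataFrame) -> list[EvaluationRecord]:
    records = []
    for row in table.itertuples():
        flag = getattr(row, "anomaly_flag", "")
        records.append(
            EvaluationRecord(
                study=str(row.study),
                population=str(row.population),
                parameter=str(row.parameter),
                unit=str(row.unit),
                dose=str(row.dose),
                observed=float(row.observed),
                predicted=float(row.predicted),
                anomaly_flag="" if pd.isna(flag) else str(flag),
            )
        )
    return records


def load_fixture(name: str) -> list[EvaluationRecord]:
    """Load one packaged observed/predicted table by fixture name."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    with resources.files("cefepime_pbpk").joinpath(f"data/fixtures/{name}.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#", dtype={"dose": str})
    return _records_from_frame(table)


def load_records_table(path) -> list[EvaluationRecord]:
    """Load a user-supplied observed/predicted table (fixture format)."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"dose": str})
    required = {"study", "population", "parameter", "unit", "dose", "observed", "predicted"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"evaluation table missing columns: {sorted(missing)}")
    return _records_from_frame(table)


def load_all_fixtures() -> list[EvaluationRecord]:
    records: list[EvaluationRecord] = []
    for name in FIXTURE_NAMES:
        records.extend(load_fixture(name))
    return records


def paper_checks() -> pd.DataFrame:
    """Recompute every published summary statistic that the packaged tables
    support, next to its printed value.

    Returns a frame with columns check, statistic, printed, recomputed,
    abs_error, passed (tolerance 0.01 absolute on ratio statistics and on
    the printed precision of the column means).
    """
    records = load_all_fixtures()
    by_pop: dict[str, list[EvaluationRecord]] = {}
    for rec in records:
        by_pop.setdefault(rec.population, []).append(rec)

    with resources.files("cefepime_pbpk").joinpath("data/fixtures/printed_summaries.tsv").open() as fh:
        expected = pd.read_csv(fh, sep="\t", comment="#")

    rows = []
    for row in expected.itertuples():
        populations = str(row.populations).split("+")
        group = [
            rec
            for pop in populations
            for rec in by_pop.get(pop, [])
            if rec.parameter == row.parameter
        ]
        if not group:
            raise RuntimeError(f"no fixture rows behind check {row.check!r}")
        ratios = [rec.ratio for rec in group]
        statistic = row.statistic
        if statistic == "mean_ratio":
            value = mean_ratio(ratios)[0]
        elif statistic == "afe":
            value = afe(ratios)
        elif statistic == "mean_observed":
            value = float(np.mean([rec.observed for rec in group]))
        elif statistic == "mean_predicted":
            value = float(np.mean([rec.predicted for rec in group]))
        else:
            raise RuntimeError(f"unknown statistic {statistic!r}")
        printed = float(row.printed_value)
        tol = 0.01 if statistic in ("mean_ratio", "afe") else 0.01
        err = abs(value - printed)
        rows.append(
            {
                "check": row.check,
                "statistic": statistic,
                "parameter": row.parameter,
                "n": len(group),
                "printed": printed,
                "recomputed": value,
                "abs_error": err,
                "passed": bool(err <= tol),
            }
        )
    return pd.DataFrame(rows)
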