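"""Domain types and CSV I/O for aggregate (study-level) trial data.

The unit of analysis is a placebo *arm*: one row per (study, time point)
holding the mean change from baseline in ADAS-cog, the per-time-point
analysed sample size, and per-study covariates.  Baseline rows (t = 0,
change = 0) are not stored: change-from-baseline is identically zero at
t = 0 and carries no information under the sqrt(N)-weighted residual.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ArmObservation",
    "StudyArm",
    "TrialSet",
    "Violation",
    "ValidationReport",
    "read_trials",
    "write_trials",
    "validate_trials",
    "filter_modeling_window",
    "REGIONS",
    "DEFAULT_COVARIATE_REFS",
]

logger = logging.getLogger(__name__)

REGIONS = (
    "International",
    "NorthAmerica",
    "EuropeOceania",
    "EastAsia",
    "MiddleAsia",
    "SouthAmerica",
)

#: Reference covariate profile (study-level medians) used for
#: normalisation of covariate functions and for covariate correction.
DEFAULT_COVARIATE_REFS = {"baseline_adas": 24.5, "baseline_age": 73.5}

ERA_SPLIT_YEAR = 2008
IMPUTATION_FLAGS = ("OC", "LOCF", "unknown")


class TrialFormatError(ValueError):
    """Input table does not conform to the expected dialect."""


@dataclass(frozen=True)
class ArmObservation:
    """One reported time point of a placebo arm."""

    time: float          # weeks since randomisation, > 0
    mean_change: float   # points on ADAS-cog, positive = worsening
    n: int               # analysed sample size at this time
    imputation: str = "unknown"


@dataclass(frozen=True)
class StudyArm:
    """One study's placebo arm with covariates and longitudinal means."""

    study_id: str
    baseline_adas: float
    baseline_age: float
    randomized_n: int
    observations: tuple[ArmObservation, ...]
    publication_year: int | None = None
    era: str | None = None
    add_on: bool | None = None
    region: str = "Unlabeled"
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        if self.era is None and self.publication_year is not None:
            era = "pre2008" if self.publication_year < ERA_SPLIT_YEAR else "post2008"
            object.__setattr__(self, "era", era)

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations])

    def covariate(self, name: str) -> float:
        """Numeric covariate lookup; dichotomous stratifiers map to 0/1."""
        if name == "baseline_adas":
            return self.baseline_adas
        if name == "baseline_age":
            return self.baseline_age
        if name == "add_on":
            return float(self.add_on) if self.add_on is not None else math.nan
        if name == "era":
            return {"pre2008": 0.0, "post2008": 1.0}.get(self.era, math.nan)
        if name == "publication_year":
            return float(self.publication_year) if self.publication_year else math.nan
        return float(self.extras.get(name, math.nan))

    def stratum(self, name: str) -> str:
        if name == "region":
            return self.region if self.region in REGIONS else "Unlabeled"
        if name == "era":
            return self.era or "unknown"
        if name == "add_on":
            if self.add_on is None:
                return "unknown"
            return "add_on" if self.add_on else "non_add_on"
        raise KeyError(f"unknown stratifier {name!r}")


@dataclass
class TrialSet:
    """A collection of placebo arms plus reference covariate values."""

    arms: list[StudyArm]
    covariate_refs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_REFS))

    def __post_init__(self) -> None:
        self.arms = list(self.arms)

    def __len__(self) -> int:
        return len(self.arms)

    def __iter__(self):
        return iter(self.arms)

    @property
    def n_observations(self) -> int:
        return sum(len(a.observations) for a in self.arms)

    def reference(self, name: str) -> float:
        """Reference value: configured ref, else the study-level median."""
        if name in self.covariate_refs:
            return self.covariate_refs[name]
        vals = np.array([a.covariate(name) for a in self.arms])
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise KeyError(f"no reference available for covariate {name!r}")
        return float(np.median(vals))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm in self.arms:
            for obs in arm.observations:
                rows.append({
                    "study_id": arm.study_id,
                    "time_weeks": obs.time,
                    "mean_change": obs.mean_change,
                    "n": obs.n,
                    "imputation": obs.imputation,
                    "baseline_adas": arm.baseline_adas,
                    "baseline_age": arm.baseline_age,
                    "randomized_n": arm.randomized_n,
                    "publication_year": arm.publication_year,
                    "era": arm.era,
                    "add_on": arm.add_on,
                    "region": arm.region,
                    **{k: v for k, v in arm.extras.items()},
                })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Violation:
    study_id: str
    rule: str
    message: str


ValidationReport = list  # list[Violation]

REQUIRED_COLUMNS = ("study_id", "time_weeks", "mean_change", "n",
                    "baseline_adas", "baseline_age")
OPTIONAL_COLUMNS = ("randomized_n", "publication_year", "era", "add_on",
                    "region", "imputation")
KNOWN_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS


def read_trials(path, dialect: Mapping[str, str] | None = None,
                covariate_refs: Mapping[str, float] | None = None) -> TrialSet:
    """Read a long-format trial CSV (one row per study-time point).

    ``dialect`` maps canonical column names to the file's column names.
    Unrecognised columns are carried as extra per-study covariates.
    Observations are sorted by time within each arm regardless of row
    order in the file.
    """
    dialect = dict(dialect or {})
    colmap = {canon: dialect.get(canon, canon) for canon in KNOWN_COLUMNS}
    df = pd.read_csv(path)
    missing = [colmap[c] for c in REQUIRED_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise TrialFormatError(f"missing required column(s): {', '.join(missing)}")

    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    for col in ("time_weeks", "mean_change"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialFormatError(
                f"non-numeric value in column {col!r} at row {row}")
        df[col] = pd.to_numeric(df[col])

    extra_cols = [c for c in df.columns if c not in KNOWN_COLUMNS]
    arms = []
    for study_id, g in df.groupby("study_id", sort=False):
        g = g.sort_values("time_weeks")
        first = g.iloc[0]
        obs = tuple(
            ArmObservation(
                time=float(r.time_weeks),
                mean_change=float(r.mean_change),
                n=int(r.n),
                imputation=str(r.imputation) if "imputation" in g.columns
                and pd.notna(r.imputation) else "unknown",
            )
            for r in g.itertuples()
        )
        randomized_n = (int(first["randomized_n"])
                        if "randomized_n" in g.columns and pd.notna(first.get("randomized_n"))
                        else int(max(o.n for o in obs)))
        year = (int(first["publication_year"])
                if "publication_year" in g.columns and pd.notna(first.get("publication_year"))
                else None)
        add_on = None
        if "add_on" in g.columns and pd.notna(first.get("add_on")):
            add_on = bool(first["add_on"]) if not isinstance(first["add_on"], str) \
                else first["add_on"].strip().lower() in ("1", "true", "yes")
        extras = {c: float(first[c]) if pd.notna(first[c]) else math.nan
                  for c in extra_cols
                  if isinstance(first[c], (int, float, np.integer, np.floating))
                  or pd.isna(first[c])}
        arms.append(StudyArm(
            study_id=str(study_id),
            baseline_adas=float(first["baseline_adas"]),
            baseline_age=float(first["baseline_age"]),
            randomized_n=randomized_n,
            observations=obs,
            publication_year=year,
            era=str(first["era"]) if "era" in g.columns and pd.notna(first.get("era")) else None,
            add_on=add_on,
            region=str(first["region"]) if "region" in g.columns
            and pd.notna(first.get("region")) else "Unlabeled",
            extras=extras,
        ))
    refs = dict(DEFAULT_COVARIATE_REFS)
    if covariate_refs:
        refs.update(covariate_refs)
    return TrialSet(arms=arms, covariate_refs=refs)


def write_trials(ts: TrialSet, path) -> None:
    """Write the TrialSet in the same long CSV dialect read_trials expects."""
    ts.to_frame().to_csv(path, index=False)


def _check_arm(arm: StudyArm) -> Iterable[Violation]:
    if not arm.randomized_n > 10:
        yield Violation(arm.study_id, "min-sample-size",
                        f"randomized_n = {arm.randomized_n} (inclusion requires > 10)")
    if not 0 < arm.baseline_adas < 70:
        yield Violation(arm.study_id, "adas-range",
                        f"baseline_adas = {arm.baseline_adas} outside (0, 70)")
    if not np.isfinite(arm.baseline_adas) or not np.isfinite(arm.baseline_age):
        yield Violation(arm.study_id, "missing-covariate",
                        "baseline_adas and baseline_age are required")
    times = arm.times
    if len(times) == 0:
        yield Violation(arm.study_id, "no-observations", "arm has no observations")
    if np.any(times <= 0):
        yield Violation(arm.study_id, "time-positive", "observation times must be > 0")
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        yield Violation(arm.study_id, "time-sorted",
                        "observation times must be strictly increasing")
    for obs in arm.observations:
        if obs.n < 1:
            yield Violation(arm.study_id, "obs-n", f"n = {obs.n} at t = {obs.time}")
        if not np.isfinite(obs.mean_change):
            yield Violation(arm.study_id, "mean-change-finite",
                            f"non-finite mean change at t = {obs.time}")


def validate_trials(ts: TrialSet) -> ValidationReport:
    """Collect invariant violations; an empty report means a clean dataset."""
    report: ValidationReport = []
    seen: set[str] = set()
    for arm in ts.arms:
        if arm.study_id in seen:
            report.append(Violation(arm.study_id, "duplicate-id",
                                    "study_id appears more than once"))
        seen.add(arm.study_id)
        report.extend(_check_arm(arm))
    return report


def filter_modeling_window(ts: TrialSet, max_weeks: float = 104.0) -> TrialSet:
    """Drop observations beyond the modelling window (default 2 years).

    Long-term observations would bias the linear progression-rate
    estimate, so only data within ``max_weeks`` are modelled.  Arms left
    without observations are dropped (counted in the module log).
    """
    if not max_weeks > 0:
        raise ValueError("max_weeks must be > 0")
    kept, dropped_arms, dropped_obs = [], 0, 0
    for arm in ts.arms:
        obs = tuple(o for o in arm.observations if o.time <= max_weeks)
        dropped_obs += len(arm.observations) - len(obs)
        if not obs:
            dropped_arms += 1
            continue
        kept.append(arm if len(obs) == len(arm.observations)
                    else replace(arm, observations=obs))
    if dropped_obs or dropped_arms:
        logger.info("modeling window %.0f weeks: dropped %d observation(s), "
                    "%d arm(s)", max_weeks, dropped_obs, dropped_arms)
    return TrialSet(arms=kept, covariate_refs=dict(ts.covariate_refs))
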