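"""Domain types and cohort / group-counts I/O.

A cohort is carried as a :class:`pandas.DataFrame` with the canonical
columns listed in :data:`COHORT_COLUMNS`; :class:`ParticipantRecord` is the
single-row view used by scalar operations.  Group-level aggregates (the
shape of a per-race eligibility/incidence summary table) are carried by
:class:`GroupCountsTable` and round-trip through a long-form CSV with
columns ``group, measure, criterion, value``.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RACE_CATEGORIES = (
    "african_american",
    "japanese_american",
    "latino",
    "nhpi",
    "white",
)

SEX_CATEGORIES = ("male", "female")
SMOKING_STATUS_CATEGORIES = ("current", "former")

#: Canonical cohort column order (writer output, reader default schema).
COHORT_COLUMNS = (
    "id",
    "race_ethnicity",
    "age",
    "sex",
    "education",
    "bmi",
    "copd_emphysema",
    "personal_cancer_history",
    "family_history_lung_cancer",
    "smoking_status",
    "intensity",
    "duration",
    "quit_years",
    "pack_years",
    "lung_cancer_6yr",
)

_BOOL_COLUMNS = (
    "copd_emphysema",
    "personal_cancer_history",
    "family_history_lung_cancer",
    "lung_cancer_6yr",
)

#: Relative tolerance for the pack-years vs (intensity/20)*duration check.
PACK_YEARS_RTOL = 0.15


@dataclass
class ParticipantRecord:
    """One cohort member: demographics, smoking history, 6-year outcome.

    The study population is ever-smokers only; never-smokers are rejected at
    read time.  ``quit_years`` is 0 exactly for current smokers.
    """

    id: str
    race_ethnicity: str
    age: float
    sex: str
    education: int
    bmi: float
    copd_emphysema: bool
    personal_cancer_history: bool
    family_history_lung_cancer: bool
    smoking_status: str
    intensity: float
    duration: float
    quit_years: float
    pack_years: float
    lung_cancer_6yr: bool

    def to_dict(self) -> dict:
        return asdict(self)


class CohortValidationError(ValueError):
    """Fatal cohort-level problem (unresolvable column, no valid rows)."""


def derive_pack_years(intensity: float, duration: float) -> float:
    """Pack-years from cigarettes/day and smoking years (20 cigarettes/pack)."""
    return (intensity / 20.0) * duration


# ---------------------------------------------------------------------------
# cohort reading / writing


def _coerce_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "0": False, "1": True, "false": False, "true": True,
        "f": False, "t": True, "no": False, "yes": True,
    }
    def one(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, float, np.integer, np.floating)) and not pd.isna(v):
            return bool(int(v))
        if isinstance(v, str):
            key = v.strip().lower()
            if key in mapping:
                return mapping[key]
        return None
    return series.map(one)


def validate_cohort_row(row: Mapping) -> list[str]:
    """Reason codes for which this row must be rejected (empty = valid)."""
    reasons: list[str] = []
    race = row.get("race_ethnicity")
    if race is None or (isinstance(race, float) and np.isnan(race)) or race == "":
        reasons.append("missing_race")
    elif race not in RACE_CATEGORIES:
        reasons.append("unknown_race")

    status = row.get("smoking_status")
    if status in ("never",):
        reasons.append("never_smoker")
    elif status not in SMOKING_STATUS_CATEGORIES:
        reasons.append("missing_smoking_data")
    else:
        intensity = row.get("intensity")
        duration = row.get("duration")
        if intensity is None or pd.isna(intensity) or intensity <= 0:
            reasons.append("missing_smoking_data")
        if duration is None or pd.isna(duration) or duration < 0:
            reasons.append("missing_smoking_data")

    for col in ("age", "sex", "education", "bmi"):
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            reasons.append(f"missing_{col}")
    sex = row.get("sex")
    if sex is not None and sex not in SEX_CATEGORIES and "missing_sex" not in reasons:
        reasons.append("invalid_sex")
    return sorted(set(reasons))


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a delimited-text cohort file into the canonical frame.

    Parameters
    ----------
    path
        CSV (default) or TSV file with a header row.
    schema
        Optional map from canonical column name to the header name used in
        the file.  Columns not mentioned are looked up under their canonical
        name.
    sep
        Field separator; autodetected from the extension when ``None``
        (``.tsv``/``.tab`` -> tab, else comma).

    Returns
    -------
    (cohort, rejects)
        ``cohort`` holds the valid rows with canonical columns and dtypes;
        ``rejects`` has the original row index plus a ``reject_reason``
        column with semicolon-joined reason codes.  Rows are rejected — not
        fatal — for missing race, missing smoking data, or a never-smoker
        status, mirroring the usual cohort exclusions.

    Raises
    ------
    CohortValidationError
        If a required column cannot be resolved in the header.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype={"id": str})

    schema = dict(schema or {})
    rename = {}
    for canonical in COHORT_COLUMNS:
        source = schema.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical not in ("pack_years", "copd_emphysema", "id"):
            raise CohortValidationError(
                f"column for {canonical!r} (header {source!r}) not found in {path.name}"
            )
    df = raw.rename(columns=rename)

    if "id" not in df.columns:
        df["id"] = [f"row{i}" for i in range(len(df))]
    if "copd_emphysema" not in df.columns:
        # the risk model needs a COPD flag even when the source table lacks one
        df["copd_emphysema"] = False
        logger.warning("copd_emphysema absent: imputed false for %d rows", len(df))
    if "pack_years" not in df.columns:
        df["pack_years"] = np.nan

    for col in _BOOL_COLUMNS:
        df[col] = _coerce_bool(df[col])

    reasons_per_row = df.apply(validate_cohort_row, axis=1)

    # pack-years: derive when absent, cross-check when present
    derived = derive_pack_years(
        pd.to_numeric(df["intensity"], errors="coerce"),
        pd.to_numeric(df["duration"], errors="coerce"),
    )
    py = pd.to_numeric(df["pack_years"], errors="coerce")
    inconsistent = (
        py.notna()
        & derived.notna()
        & (derived > 0)
        & ((py - derived).abs() > PACK_YEARS_RTOL * derived)
    )
    for i in df.index[inconsistent]:
        reasons_per_row[i] = sorted(set(reasons_per_row[i]) | {"inconsistent_pack_years"})
    df["pack_years"] = py.where(py.notna(), derived)

    # quit-years repair: current smokers carry quit_years 0 by definition
    qy = pd.to_numeric(df["quit_years"], errors="coerce")
    current = df["smoking_status"] == "current"
    n_repair = int(((qy != 0) & current).sum() + (qy.isna() & current).sum())
    if n_repair:
        logger.warning("repaired quit_years to 0 for %d current smokers", n_repair)
    qy = qy.mask(current, 0.0)
    former_missing = qy.isna() & (df["smoking_status"] == "former")
    for i in df.index[former_missing]:
        reasons_per_row[i] = sorted(set(reasons_per_row[i]) | {"missing_smoking_data"})
    df["quit_years"] = qy

    bad = reasons_per_row.map(len) > 0
    rejects = pd.DataFrame(
        {
            "id": df.loc[bad, "id"],
            "reject_reason": reasons_per_row[bad].map(";".join),
        }
    )
    if bad.any():
        logger.warning("rejected %d of %d rows", int(bad.sum()), len(df))
    cohort = df.loc[~bad, list(COHORT_COLUMNS)].reset_index(drop=True)
    cohort = _finalize_dtypes(cohort)
    return cohort, rejects


def _finalize_dtypes(cohort: pd.DataFrame) -> pd.DataFrame:
    cohort = cohort.copy()
    for col in ("age", "bmi", "intensity", "duration", "quit_years", "pack_years"):
        cohort[col] = pd.to_numeric(cohort[col]).astype(float)
    cohort["education"] = pd.to_numeric(cohort["education"]).astype(int)
    for col in _BOOL_COLUMNS:
        cohort[col] = cohort[col].astype(bool)
    cohort["id"] = cohort["id"].astype(str)
    return cohort


def write_cohort(cohort: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a cohort frame as delimited text (booleans as 0/1).

    Enforces the current-smoker quit-years convention before writing.
    """
    out = cohort.loc[:, list(COHORT_COLUMNS)].copy()
    out.loc[out["smoking_status"] == "current", "quit_years"] = 0.0
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, sep=sep, index=False)


def cohort_to_records(cohort: pd.DataFrame) -> list[ParticipantRecord]:
    """Materialise ParticipantRecord objects from a cohort frame."""
    return [ParticipantRecord(**row) for row in cohort.to_dict(orient="records")]


def records_to_cohort(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([r.to_dict() for r in records], columns=list(COHORT_COLUMNS))
    return _finalize_dtypes(frame) if len(frame) else frame


# ---------------------------------------------------------------------------
# group counts


OVERALL = "overall"


class GroupCountsError(ValueError):
    """Fatal group-counts inconsistency (e.g. overall row != column sum)."""


@dataclass
class GroupCountsTable:
    """Per-race aggregates: N, 6-year incident cases, eligible per criterion.

    ``groups`` excludes the overall row; the overall row must equal the
    column sums and is checked at construction.
    """

    n_total: dict[str, int]
    incident_cases_6yr: dict[str, int]
    eligible: dict[str, dict[str, int]]  # criterion -> group -> count

    def __post_init__(self) -> None:
        self.validate()

    @property
    def groups(self) -> list[str]:
        return [g for g in self.n_total if g != OVERALL]

    @property
    def criteria(self) -> list[str]:
        return list(self.eligible)

    def validate(self) -> None:
        groups = self.groups
        for name, col in self._columns():
            for g, v in col.items():
                if not (0 <= v <= self.n_total[g]):
                    raise GroupCountsError(
                        f"{name}[{g}] = {v} outside [0, n_total={self.n_total[g]}]"
                    )
            if OVERALL in col:
                total = sum(col[g] for g in groups)
                if col[OVERALL] != total:
                    raise GroupCountsError(
                        f"overall row mismatch in column {name!r}: "
                        f"overall={col[OVERALL]} but groups sum to {total}"
                    )

    def _columns(self):
        yield "incident_cases_6yr", self.incident_cases_6yr
        for crit, col in self.eligible.items():
            yield f"eligible[{crit}]", col

    def row_percent(self, group: str) -> float:
        """Group share of the overall cohort, in percent."""
        return 100.0 * self.n_total[group] / self.n_total[OVERALL]

    def eligibility_percent(self, group: str, criterion: str) -> float:
        return 100.0 * self.eligible[criterion][group] / self.n_total[group]

    def incidence_percent(self, group: str) -> float:
        return 100.0 * self.incident_cases_6yr[group] / self.n_total[group]

    def to_frame(self) -> pd.DataFrame:
        """Long-form frame with columns group, measure, criterion, value."""
        rows = []
        for g, v in self.n_total.items():
            rows.append((g, "n_total", "", v))
        for g, v in self.incident_cases_6yr.items():
            rows.append((g, "incident_cases_6yr", "", v))
        for crit, col in self.eligible.items():
            for g, v in col.items():
                rows.append((g, "eligible", crit, v))
        return pd.DataFrame(rows, columns=["group", "measure", "criterion", "value"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_group_counts(path: str | Path) -> GroupCountsTable:
    """Read a long-form group-counts CSV (group, measure, criterion, value).

    Raises :class:`GroupCountsError` when any column's overall row does not
    equal the sum over groups, naming the offending column.
    """
    df = pd.read_csv(path, keep_default_na=False)
    required = {"group", "measure", "criterion", "value"}
    if not required.issubset(df.columns):
        raise GroupCountsError(f"group-counts file must have columns {sorted(required)}")
    n_total: dict[str, int] = {}
    cases: dict[str, int] = {}
    eligible: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        g, measure, crit, value = (
            row["group"],
            row["measure"],
            str(row["criterion"]),
            int(row["value"]),
        )
        if measure == "n_total":
            n_total[g] = value
        elif measure == "incident_cases_6yr":
            cases[g] = value
        elif measure == "eligible":
            eligible.setdefault(crit, {})[g] = value
        else:
            raise GroupCountsError(f"unknown measure {measure!r}")
    groups = [g for g in n_total if g != OVERALL]
    if OVERALL in n_total:
        total = sum(n_total[g] for g in groups)
        if n_total[OVERALL] != total:
            raise GroupCountsError(
                f"overall row mismatch in column 'n_total': "
                f"overall={n_total[OVERALL]} but groups sum to {total}"
            )
    return GroupCountsTable(n_total=n_total, incident_cases_6yr=cases, eligible=eligible)


#: Criterion names used by the packaged multiethnic-cohort counts fixture.
USPSTF_2021 = "uspstf_2021"
USPSTF_2013 = "uspstf_2013"
RISK_BASED = "plco_update_risk_1.3pct"


def packaged_counts_path() -> Path:
    from importlib import resources

    return Path(resources.files("lungscreen").joinpath("data", "mec_table1_counts.csv"))


def load_packaged_counts() -> GroupCountsTable:
    """Published per-race eligibility and incidence counts for the
    105 261-member multiethnic study cohort (the worked-example fixture)."""
    return read_group_counts(packaged_counts_path())


# ---------------------------------------------------------------------------
# analysis configuration


@dataclass
class AnalysisConfig:
    """Knobs shared by the eligibility / disparity stages.

    ``per_test_alpha`` is the familywise level divided by the number of
    non-reference comparisons (Bonferroni).
    """

    reference_group: str = "white"
    alpha_familywise: float = 0.05
    n_comparisons: int = 4
    risk_thresholds: tuple[float, ...] = (0.013,)
    sensitivity_thresholds: tuple[float, ...] = (0.01, 0.0151, 0.017, 0.02)
    age_window: tuple[float, float] = (50.0, 80.0)
    cv_folds: int = 10
    rng_seed: int = 0

    @property
    def per_test_alpha(self) -> float:
        return self.alpha_familywise / self.n_comparisons

    def __post_init__(self) -> None:
        for t in tuple(self.risk_thresholds) + tuple(self.sensitivity_thresholds):
            if not (0.0 < t < 1.0):
                raise ValueError(f"risk threshold {t} outside (0, 1)")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")
        lo, hi = self.age_window
        if not lo < hi:
            raise ValueError("age_window must satisfy lo < hi")
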