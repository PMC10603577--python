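"""Logistic absolute-risk model evaluation (PLCOm2012 family).

A model is a :class:`CoefficientSet`: an intercept, an ordered list of
transformed covariate terms, and a map of race/ethnicity coefficients with
a single reference category at 0.  The linear predictor is

    lp = intercept + sum_j beta_j * T_j(x_j) + beta_race[race]

and the 6-year absolute risk is ``1 / (1 + exp(-lp))``.  Coefficient sets
live in versioned YAML data files, not in code, so the original model, its
recalibrated update and the merged-race variant are all consumed by the one
evaluator.

Transformations
---------------
``identity``            x
``center``              x - center
``center_scale``        (x - center) / scale
``reciprocal_scaled``   (x / scale)^-1 - center   (the nonlinear
                        smoking-intensity transform; undefined at x <= 0)
``indicator``           1[x == level] (level carried in the term)
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data_model import COHORT_COLUMNS, RACE_CATEGORIES, ParticipantRecord

logger = logging.getLogger(__name__)

_TRANSFORMATIONS = ("identity", "center", "center_scale", "reciprocal_scaled", "indicator")


class CoefficientError(ValueError):
    """Invalid coefficient file or undefined transform input."""


@dataclass(frozen=True)
class ModelTerm:
    variable: str
    coefficient: float
    transformation: str = "identity"
    center: float = 0.0
    scale: float = 1.0
    level: object | None = None

    def __post_init__(self) -> None:
        if self.transformation not in _TRANSFORMATIONS:
            raise CoefficientError(f"unknown transformation {self.transformation!r}")
        if self.variable not in COHORT_COLUMNS:
            raise CoefficientError(f"unknown variable {self.variable!r}")
        for p in (self.coefficient, self.center, self.scale):
            if not np.isfinite(p):
                raise CoefficientError(f"non-finite parameter in term {self.variable!r}")
        if self.transformation == "indicator" and self.level is None:
            raise CoefficientError(f"indicator term {self.variable!r} needs a level")

    def evaluate(self, values: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(values, dtype=float) if self.transformation != "indicator" else values
        if self.transformation == "identity":
            return x
        if self.transformation == "center":
            return x - self.center
        if self.transformation == "center_scale":
            return (x - self.center) / self.scale
        if self.transformation == "reciprocal_scaled":
            if np.any(np.asarray(x) <= 0):
                raise CoefficientError(
                    f"reciprocal_scaled transform undefined for non-positive {self.variable}"
                )
            return (np.asarray(x) / self.scale) ** -1.0 - self.center
        # indicator
        return (np.asarray(values) == self.level).astype(float)


@dataclass(frozen=True)
class CoefficientSet:
    """A logistic absolute-risk model as data.

    ``race_coefficients`` carries exactly one reference category at 0.
    A merged-race variant lists the merged categories in ``race_merge``
    (category -> category actually carrying the coefficient) instead of
    duplicating zeros.
    """

    model_name: str
    intercept: float
    terms: tuple[ModelTerm, ...]
    race_coefficients: Mapping[str, float]
    race_merge: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        refs = [r for r, b in self.race_coefficients.items() if b == 0.0]
        if len(refs) == 0:
            raise CoefficientError("no reference race (coefficient 0) in race map")
        if len(refs) > 1:
            raise CoefficientError(f"ambiguous reference: {refs}")
        for r in list(self.race_coefficients) + list(self.race_merge):
            if r not in RACE_CATEGORIES:
                raise CoefficientError(f"unknown race category {r!r}")
        for src, dst in self.race_merge.items():
            if dst not in self.race_coefficients:
                raise CoefficientError(f"race_merge target {dst!r} has no coefficient")

    @property
    def reference_race(self) -> str:
        return next(r for r, b in self.race_coefficients.items() if b == 0.0)

    def race_coefficient(self, race: str) -> float:
        race = self.race_merge.get(race, race)
        try:
            return float(self.race_coefficients[race])
        except KeyError:
            raise CoefficientError(
                f"model {self.model_name!r} has no coefficient for race {race!r}"
            ) from None

    def with_race_update(
        self, intercept_shift: float, race_coefficients: Mapping[str, float], suffix: str
    ) -> "CoefficientSet":
        """New set differing only in intercept and race coefficients."""
        return CoefficientSet(
            model_name=f"{self.model_name}{suffix}",
            intercept=self.intercept + intercept_shift,
            terms=self.terms,
            race_coefficients=dict(race_coefficients),
        )


@dataclass(frozen=True)
class RiskScore:
    linear_predictor: float
    risk: float


def logistic(lp):
    """Numerically stable inverse-logit."""
    lp = np.asarray(lp, dtype=float)
    out = np.empty_like(lp)
    pos = lp >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-lp[pos]))
    e = np.exp(lp[~pos])
    out[~pos] = e / (1.0 + e)
    return out if out.ndim else float(out)


def logit(p):
    p = np.asarray(p, dtype=float)
    out = np.log(p) - np.log1p(-p)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# loading


def _data_path(name: str) -> Path:
    return Path(resources.files("lungscreen").joinpath("data", name))


def packaged_model_path(which: str = "original") -> Path:
    """Path of a packaged coefficient file: 'original' or 'race3l'."""
    names = {"original": "plcom2012_original.yaml", "race3l": "plcom2012_race3l.yaml"}
    try:
        return _data_path(names[which])
    except KeyError:
        raise CoefficientError(f"no packaged model {which!r}") from None


def load_coefficients(path: str | Path) -> CoefficientSet:
    """Load and validate a coefficient YAML file.

    The file must carry ``schema_version: 1``; the file checksum is logged
    so a run manifest can pin the exact coefficients used.
    """
    path = Path(path)
    blob = path.read_bytes()
    doc = yaml.safe_load(blob)
    if doc.get("schema_version") != 1:
        raise CoefficientError(f"{path.name}: missing or unsupported schema_version")
    logger.info("loaded %s sha256=%s", path.name, hashlib.sha256(blob).hexdigest()[:16])
    terms = tuple(
        ModelTerm(
            variable=t["variable"],
            coefficient=float(t["coefficient"]),
            transformation=t.get("transformation", "identity"),
            center=float(t.get("center", 0.0)),
            scale=float(t.get("scale", 1.0)),
            level=t.get("level"),
        )
        for t in doc["terms"]
    )
    race = {k: float(v) for k, v in doc["race_coefficients"].items()}
    return CoefficientSet(
        model_name=doc["model_name"],
        intercept=float(doc["intercept"]),
        terms=terms,
        race_coefficients=race,
        race_merge=dict(doc.get("race_merge", {})),
    )


def save_coefficients(model: CoefficientSet, path: str | Path) -> None:
    """Write a coefficient set back to the YAML file schema."""
    doc = {
        "schema_version": 1,
        "model_name": model.model_name,
        "intercept": float(model.intercept),
        "terms": [
            {
                "variable": t.variable,
                "transformation": t.transformation,
                "center": float(t.center),
                "scale": float(t.scale),
                "coefficient": float(t.coefficient),
                **({"level": t.level} if t.level is not None else {}),
            }
            for t in model.terms
        ],
        "race_coefficients": {k: float(v) for k, v in model.race_coefficients.items()},
    }
    if model.race_merge:
        doc["race_merge"] = dict(model.race_merge)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_original_model() -> CoefficientSet:
    return load_coefficients(packaged_model_path("original"))


def load_race3l_model() -> CoefficientSet:
    return load_coefficients(packaged_model_path("race3l"))


# ---------------------------------------------------------------------------
# scoring


def linear_predictor(cohort: pd.DataFrame, model: CoefficientSet) -> np.ndarray:
    """Vectorised linear predictor over a cohort frame."""
    lp = np.full(len(cohort), model.intercept, dtype=float)
    for term in model.terms:
        lp += term.coefficient * np.asarray(
            term.evaluate(cohort[term.variable].to_numpy()), dtype=float
        )
    lp += cohort["race_ethnicity"].map(model.race_coefficient).to_numpy(dtype=float)
    return lp


def score_cohort(cohort: pd.DataFrame, model: CoefficientSet) -> pd.DataFrame:
    """Score every record; returns columns id, linear_predictor, risk."""
    lp = linear_predictor(cohort, model)
    return pd.DataFrame(
        {"id": cohort["id"].to_numpy(), "linear_predictor": lp, "risk": logistic(lp)}
    )


def compute_risk(record: ParticipantRecord, model: CoefficientSet) -> RiskScore:
    """Six-year absolute risk for one participant."""
    lp = model.intercept
    for term in model.terms:
        lp += term.coefficient * float(np.asarray(term.evaluate(getattr(record, term.variable))))
    lp += model.race_coefficient(record.race_ethnicity)
    return RiskScore(linear_predictor=lp, risk=float(logistic(lp)))


_RACE3L_MAP = {
    "japanese_american": "white",
    "latino": "white",
    "nhpi": "white",
    "african_american": "african_american",
    "white": "white",
}


def map_race3l(record: ParticipantRecord) -> ParticipantRecord:
    """Merge Asian, Hispanic and NHPI categories into the White reference.

    Pure function; African American and White records pass through.
    """
    mapped = _RACE3L_MAP.get(record.race_ethnicity)
    if mapped is None:
        raise CoefficientError(f"unknown race category {record.race_ethnicity!r}")
    if mapped == record.race_ethnicity:
        return record
    return replace(record, race_ethnicity=mapped)


def map_race3l_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    out["race_ethnicity"] = out["race_ethnicity"].map(_RACE3L_MAP)
    return out
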