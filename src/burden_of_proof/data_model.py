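"""Domain types and table IO for dose-response risk observations.

A *risk observation* is one extracted relative-risk (RR/OR/HR) estimate comparing
an alternative exposure interval (e.g. 20-30 pack-years of smoking) against a
reference interval (usually never/zero exposure), together with its reported
uncertainty, study design and risk-of-bias covariates.  Observation tables are
plain CSV, one row per dose-specific estimate; a :class:`PairConfig` describes
how a risk-outcome pair is to be modelled.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% normal quantile used to invert reported CIs

#: exposure metrics supported for continuous pairs
EXPOSURE_MEASURES = ("pack_years", "cigarettes_per_day", "binary")
DIRECTIONS = ("harmful", "protective")
MONOTONE = ("nondecreasing", "nonincreasing", "none")
STUDY_DESIGNS = (
    "prospective_cohort",
    "case_control",
    "nested_case_control",
    "cross_sectional",
)
FOLLOWUP_TYPES = ("mean", "median", "max")

#: registry of recognised risk-of-bias covariates: the six GRADE domains plus
#: the study-characteristic covariates used when modelling adjustment level.
KNOWN_BIAS_COVARIATES = (
    "representativeness",
    "exposure",
    "outcome",
    "reverse_causation",
    "confounding",
    "selection_bias",
    "subpopulation",
    "adjustment_level",
    "age_sex_adjustment",
    "exposure_definition",
)

#: fixed CSV schema (bias covariates travel as ``bias_<name>`` columns)
REQUIRED_COLUMNS = (
    "study_id",
    "effect",
    "alt_lower",
    "alt_upper",
    "ref_lower",
    "ref_upper",
)
OPTIONAL_COLUMNS = (
    "ci_lower",
    "ci_upper",
    "se_log",
    "design",
    "age_lower",
    "age_upper",
    "followup_years",
    "followup_type",
)


class SchemaError(ValueError):
    """Observation table does not follow the documented column schema."""


class ValidationError(ValueError):
    """One or more rows violate the domain invariants."""


def se_from_ci(ci_lower: float, ci_upper: float) -> float:
    """Log-scale standard error implied by a reported 95% CI of a ratio measure.

    Assumes log-normal sampling: ``se = (ln(upper) - ln(lower)) / (2 * 1.959964)``.
    """
    if not (0 < ci_lower < ci_upper):
        raise ValidationError(
            f"CI bounds must satisfy 0 < lower < upper, got ({ci_lower}, {ci_upper})"
        )
    return (math.log(ci_upper) - math.log(ci_lower)) / (2.0 * Z_95)


@dataclass(frozen=True)
class ExposureInterval:
    """A (possibly degenerate) exposure range in pack-years or cigarettes/day.

    Open-ended top categories (">x") carry an imputed finite ``upper`` and are
    flagged via ``open_ended`` so provenance is not lost.
    """

    lower: float
    upper: float
    open_ended: bool = False

    def __post_init__(self) -> None:
        if not (self.lower >= 0):
            raise ValidationError(f"interval lower must be >= 0, got {self.lower}")
        if not (self.lower <= self.upper):
            raise ValidationError(
                f"interval must satisfy lower <= upper, got [{self.lower}, {self.upper}]"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def is_point(self) -> bool:
        return self.upper == self.lower


def impute_open_upper(lower: float, typical_width: float | None = None) -> float:
    """Close an open-ended ">x" category.

    Uses ``x + w`` where ``w`` is a typical interval width from the same study,
    falling back to ``1.5 * x`` when no width information is available.
    """
    if typical_width is not None and typical_width > 0:
        return lower + typical_width
    return lower * 1.5 if lower > 0 else 1.0


@dataclass
class RiskObservation:
    """One extracted dose-specific RR/OR/HR with uncertainty and bias covariates."""

    study_id: str
    effect: float
    se_log: float
    alt: ExposureInterval
    ref: ExposureInterval
    design: str = "prospective_cohort"
    bias: dict[str, float] = field(default_factory=dict)
    ci_lower: float | None = None
    ci_upper: float | None = None
    age_lower: float | None = None
    age_upper: float | None = None
    followup_years: float | None = None
    followup_type: str | None = None

    def __post_init__(self) -> None:
        if not (self.effect > 0):
            raise ValidationError(f"effect must be > 0, got {self.effect}")
        if not (self.se_log > 0):
            raise ValidationError(f"se_log must be > 0, got {self.se_log}")
        if self.ci_lower is not None and self.ci_upper is not None:
            if not (self.ci_lower < self.effect < self.ci_upper):
                raise ValidationError(
                    f"CI ({self.ci_lower}, {self.ci_upper}) must bracket effect {self.effect}"
                )
        if self.design not in STUDY_DESIGNS:
            raise ValidationError(f"unknown study design {self.design!r}")
        for name in self.bias:
            if name not in KNOWN_BIAS_COVARIATES:
                raise SchemaError(f"unknown bias covariate {name!r}")
        if self.followup_type is not None and self.followup_type not in FOLLOWUP_TYPES:
            raise ValidationError(f"unknown followup_type {self.followup_type!r}")

    @property
    def log_effect(self) -> float:
        return math.log(self.effect)


@dataclass
class PairConfig:
    """Modelling configuration for one risk-outcome pair."""

    outcome_name: str
    exposure_measure: str = "pack_years"
    direction: str = "harmful"
    monotone: str = "nondecreasing"
    is_cvd: bool = False
    trim_fraction: float = 0.10
    n_ensemble: int = 50
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exposure_measure not in EXPOSURE_MEASURES:
            raise ValidationError(f"unknown exposure measure {self.exposure_measure!r}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")
        if self.monotone not in MONOTONE:
            raise ValidationError(f"unknown monotonicity {self.monotone!r}")
        if not (0 <= self.trim_fraction < 0.5):
            raise ValidationError("trim_fraction must lie in [0, 0.5)")
        if self.n_ensemble < 1:
            raise ValidationError("n_ensemble must be >= 1")
        if self.n_draws < 100:
            raise ValidationError("n_draws must be >= 100")

    @classmethod
    def from_json(cls, path: str | Path) -> "PairConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @property
    def is_binary(self) -> bool:
        return self.exposure_measure == "binary"


def _parse_interval(
    lower, upper, typical_width: float | None, what: str, problems: list[str], row: int
) -> ExposureInterval | None:
    try:
        lo = float(lower)
    except (TypeError, ValueError):
        problems.append(f"row {row}: {what}_lower is not a number ({lower!r})")
        return None
    open_ended = upper is None or (isinstance(upper, float) and math.isnan(upper))
    if open_ended:
        up = impute_open_upper(lo, typical_width)
    else:
        up = float(upper)
    try:
        return ExposureInterval(lo, up, open_ended=open_ended)
    except ValidationError as exc:
        problems.append(f"row {row}: {exc}")
        return None


def read_observations(path: str | Path, config: PairConfig) -> list[RiskObservation]:
    """Read and validate an observation table.

    Raises :class:`SchemaError` when required columns are absent and
    :class:`ValidationError` listing every offending row number (1-based data
    rows) when values violate the domain invariants.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if "se_log" not in df.columns and not {"ci_lower", "ci_upper"} <= set(df.columns):
        raise SchemaError("need either se_log or ci_lower/ci_upper columns")

    bias_cols = [c for c in df.columns if c.startswith("bias_")]
    for col in bias_cols:
        if col[len("bias_") :] not in KNOWN_BIAS_COVARIATES:
            raise SchemaError(f"unknown bias covariate column {col!r}")

    # typical closed alt-interval width per study, for closing ">x" categories
    closed = df.dropna(subset=["alt_upper"])
    widths = (closed["alt_upper"] - closed["alt_lower"]).groupby(closed["study_id"]).median()

    observations: list[RiskObservation] = []
    problems: list[str] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        study = str(rec["study_id"])
        tw = widths.get(rec["study_id"])
        tw = None if tw is None or pd.isna(tw) or tw <= 0 else float(tw)
        alt = _parse_interval(rec["alt_lower"], rec.get("alt_upper"), tw, "alt", problems, i)
        ref = _parse_interval(rec["ref_lower"], rec.get("ref_upper"), tw, "ref", problems, i)
        if alt is None or ref is None:
            continue
        effect = rec.get("effect")
        ci_lo, ci_up = rec.get("ci_lower"), rec.get("ci_upper")
        has_ci = ci_lo is not None and ci_up is not None and not (
            pd.isna(ci_lo) or pd.isna(ci_up)
        )
        se = rec.get("se_log")
        has_se = se is not None and not pd.isna(se)
        try:
            if effect is None or pd.isna(effect) or float(effect) <= 0:
                raise ValidationError(f"effect must be > 0, got {effect!r}")
            if has_ci:
                se_ci = se_from_ci(float(ci_lo), float(ci_up))
                if has_se and se > 0 and abs(se_ci - float(se)) > 0.01 * se_ci:
                    logger.warning(
                        "row %d: se_log %.4g disagrees with CI-implied %.4g by >1%%; CI wins",
                        i, float(se), se_ci,
                    )
                se_use = se_ci  # CI wins when both are given
            elif has_se:
                se_use = float(se)
            else:
                raise ValidationError("neither CI nor se_log supplied")
            obs = RiskObservation(
                study_id=study,
                effect=float(effect),
                se_log=se_use,
                alt=alt,
                ref=ref,
                design=str(rec.get("design", "prospective_cohort"))
                if not pd.isna(rec.get("design", "prospective_cohort"))
                else "prospective_cohort",
                bias={
                    c[len("bias_") :]: float(rec[c])
                    for c in bias_cols
                    if not pd.isna(rec[c])
                },
                ci_lower=float(ci_lo) if has_ci else None,
                ci_upper=float(ci_up) if has_ci else None,
                age_lower=None if pd.isna(rec.get("age_lower", np.nan)) else float(rec["age_lower"]),
                age_upper=None if pd.isna(rec.get("age_upper", np.nan)) else float(rec["age_upper"]),
                followup_years=None
                if pd.isna(rec.get("followup_years", np.nan))
                else float(rec["followup_years"]),
                followup_type=None
                if pd.isna(rec.get("followup_type", np.nan))
                else str(rec["followup_type"]),
            )
        except (ValidationError, SchemaError, TypeError) as exc:
            problems.append(f"row {i}: {exc}")
            continue
        observations.append(obs)
    if problems:
        raise ValidationError("invalid observation rows:\n" + "\n".join(problems))
    return observations


def observations_to_frame(observations: Sequence[RiskObservation]) -> pd.DataFrame:
    """Flatten observations back to the documented CSV schema."""
    bias_names = sorted({n for o in observations for n in o.bias})
    rows = []
    for o in observations:
        row = {
            "study_id": o.study_id,
            "effect": o.effect,
            "ci_lower": o.ci_lower,
            "ci_upper": o.ci_upper,
            "se_log": o.se_log,
            "alt_lower": o.alt.lower,
            "alt_upper": np.nan if o.alt.open_ended else o.alt.upper,
            "ref_lower": o.ref.lower,
            "ref_upper": np.nan if o.ref.open_ended else o.ref.upper,
            "design": o.design,
            "age_lower": o.age_lower,
            "age_upper": o.age_upper,
            "followup_years": o.followup_years,
            "followup_type": o.followup_type,
        }
        for name in bias_names:
            row[f"bias_{name}"] = o.bias.get(name, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_observations(
    observations: Sequence[RiskObservation], path: str | Path
) -> None:
    observations_to_frame(observations).to_csv(path, index=False, float_format="%.17g")
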