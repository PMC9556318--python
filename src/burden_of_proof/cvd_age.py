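"""Age-specific risk curves for cardiovascular outcomes.

Smoking risk on cardiovascular outcomes attenuates with age.  The reference
dose-response curve for a CVD outcome is fitted on all dose-specific data
regardless of age; this module (i) locates the age group that reference curve
represents (the precision-weighted mean age of the dose-specific data snapped
to its 5-year bin), (ii) fits the age pattern of excess risk (RR - 1) from
age-group-specific binary-smoking RRs, (iii) converts that pattern into age
attenuation factors AF relative to the reference group, and (iv) adjusts the
reference curve draw-by-draw,

    RR_age(x) = (RR_ref(x) - 1) * AF_age + 1,

so the attenuation uncertainty propagates into the age-specific curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .data_model import RiskObservation, ValidationError, se_from_ci
from .heterogeneity import FitContext, fit_variance_components, pd_unique

#: exposure-definition levels for the age-pattern bias covariate
EXPOSURE_DEFINITIONS = ("current", "former", "ever")


@dataclass(frozen=True)
class AgeGroup:
    """A 5-year age bin such as 55-59 (inclusive of both printed endpoints)."""

    lower: int
    upper: int

    def __post_init__(self) -> None:
        if self.lower < 30:
            raise ValidationError("age groups start at 30-34")
        if self.upper - self.lower != 4:
            raise ValidationError("age groups are 5-year bins (e.g. 55-59)")

    @property
    def label(self) -> str:
        return f"{self.lower}-{self.upper}"

    @property
    def midpoint(self) -> float:
        return self.lower + 2.5

    @classmethod
    def from_age(cls, age: float) -> "AgeGroup":
        if age < 30:
            raise ValidationError(f"age {age} below the adult range (>=30)")
        lower = 30 + 5 * int((age - 30) // 5)
        return cls(lower, lower + 4)


def _assigned_age(obs: RiskObservation) -> float | None:
    """Age a risk estimate refers to, per study design.

    Cohorts: mean baseline age plus mean/median follow-up (half the follow-up
    when only its maximum was reported).  Case-control designs: baseline mean
    age, i.e. the midpoint of the reported range.
    """
    if obs.age_lower is None or obs.age_upper is None:
        return None
    mid = 0.5 * (obs.age_lower + obs.age_upper)
    if obs.design in ("prospective_cohort", "nested_case_control") and obs.followup_years:
        fu = obs.followup_years
        if obs.followup_type == "max":
            fu = fu / 2.0
        return mid + fu
    return mid


def reference_age_group(observations: Sequence[RiskObservation]) -> AgeGroup:
    """Age group of the reference risk curve.

    Mean of the per-observation assigned ages weighted by the reciprocal of
    each observation's standard error, snapped to its 5-year bin.
    """
    ages, weights = [], []
    for obs in observations:
        age = _assigned_age(obs)
        if age is not None:
            ages.append(age)
            weights.append(1.0 / obs.se_log)
    if not ages:
        raise ValidationError(
            "no observations carry age metadata; run in non-age-specific mode"
        )
    mean_age = float(np.average(ages, weights=weights))
    return AgeGroup.from_age(mean_age)


@dataclass
class AgeRiskCurve:
    """Fitted age pattern of excess risk with fixed-effect uncertainty only."""

    knots: np.ndarray          # full clamped knot vector for the age spline
    degree: int
    coef: np.ndarray           # spline coefficients followed by covariate effects
    cov: np.ndarray            # covariance of the fixed effects
    n_spline: int
    covariate_names: tuple[str, ...]
    age_range: tuple[float, float]
    gamma_age: float = 0.0     # between-study slope variance (not propagated)

    def _basis(self, ages: np.ndarray) -> np.ndarray:
        ages = np.clip(np.asarray(ages, dtype=float), *self.age_range)
        return BSpline.design_matrix(
            ages, self.knots, self.degree, extrapolate=False
        ).toarray()

    def predict_excess(self, ages, coef: np.ndarray | None = None) -> np.ndarray:
        """Excess risk RR-1 at given ages, covariates at reference (current smokers)."""
        b = self.coef if coef is None else coef
        return self._basis(np.atleast_1d(ages)) @ b[: self.n_spline]

    def sample_coefs(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Fixed-effect coefficient draws (between-study heterogeneity excluded)."""
        return rng.multivariate_normal(self.coef, self.cov, size=n_draws)


def _age_se_natural(df: pd.DataFrame) -> np.ndarray:
    """Natural-scale SE of excess risk from CI or log-scale SE (delta method)."""
    if {"ci_lower", "ci_upper"} <= set(df.columns) and df["ci_lower"].notna().all():
        se_log = np.array(
            [se_from_ci(lo, up) for lo, up in zip(df["ci_lower"], df["ci_upper"])]
        )
    else:
        se_log = df["se_log"].to_numpy(dtype=float)
    return df["effect"].to_numpy(dtype=float) * se_log


def fit_age_pattern(age_data: pd.DataFrame, *, n_interior: int = 2) -> AgeRiskCurve:
    """Fit the age pattern of excess risk from age-specific binary-smoking RRs.

    ``age_data`` columns: study_id, effect (RR), ci_lower/ci_upper or se_log,
    age_lower, age_upper, exposure_definition (current|former|ever).  The model
    is a quadratic spline on age plus exposure-definition covariates, with a
    study-specific random slope on age; predictions exclude the between-study
    component.
    """
    required = {"study_id", "effect", "age_lower", "age_upper"}
    if not required <= set(age_data.columns):
        raise ValidationError(f"age table needs columns {sorted(required)}")
    ages = 0.5 * (age_data["age_lower"] + age_data["age_upper"]).to_numpy(dtype=float)
    if len(np.unique(5 * np.round(ages / 5))) < 3:
        raise ValidationError("need at least 3 distinct age groups to fit an age pattern")
    y = age_data["effect"].to_numpy(dtype=float) - 1.0  # excess risk
    se = _age_se_natural(age_data)

    lo, hi = float(ages.min()), float(ages.max())
    interior = np.quantile(ages, np.linspace(0, 1, n_interior + 2)[1:-1])
    interior = interior[(interior > lo) & (interior < hi)]
    degree = 2
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    B = BSpline.design_matrix(ages, knots, degree, extrapolate=False).toarray()
    n_spline = B.shape[1]

    cov_names: list[str] = []
    cols = [B]
    if "exposure_definition" in age_data.columns:
        defs = age_data["exposure_definition"].fillna("current")
        for level in EXPOSURE_DEFINITIONS[1:]:
            col = (defs == level).to_numpy(dtype=float)
            if col.any():
                cols.append(col[:, None])
                cov_names.append(level)
    X = np.hstack(cols)

    studies = age_data["study_id"].astype(str).to_numpy()
    blocks = [np.flatnonzero(studies == sid) for sid in pd_unique(studies)]
    age_scaled = (ages - ages.mean()) / 10.0  # random-slope covariate
    ctx = FitContext(y=y, X=X, s=age_scaled, se2=se**2, blocks=blocks)
    b, cov_b, _tau2, gamma, _nll = fit_variance_components(ctx)
    return AgeRiskCurve(
        knots=knots,
        degree=degree,
        coef=b,
        cov=cov_b,
        n_spline=n_spline,
        covariate_names=tuple(cov_names),
        age_range=(lo, hi),
        gamma_age=gamma,
    )


@dataclass
class AgeAttenuation:
    """Draw-level attenuation factors AF per age group (AF at reference == 1)."""

    reference_group: AgeGroup
    age_groups: list[AgeGroup]
    af_draws: np.ndarray  # n_draws x n_groups
    n_rejected: int = 0

    def mean_af(self) -> np.ndarray:
        return self.af_draws.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = np.percentile(self.af_draws, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "age_group": [g.label for g in self.age_groups],
                "af_mean": self.mean_af(),
                "af_lower": lo,
                "af_upper": hi,
            }
        )


def attenuation_factors(
    curve: AgeRiskCurve,
    reference_group: AgeGroup,
    n_draws: int,
    rng: np.random.Generator | None = None,
    age_groups: Sequence[AgeGroup] | None = None,
) -> AgeAttenuation:
    """Draws of AF_age = excess(age) / excess(reference age).

    Draws whose reference excess is nonpositive carry no usable ratio; they are
    rejected, resampled and counted.  AF at the reference group is exactly 1.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lo, hi = curve.age_range
    if not (lo <= reference_group.midpoint <= hi):
        raise ValidationError("reference group lies outside the fitted age range")
    if age_groups is None:
        first = AgeGroup.from_age(max(lo, 30.0))
        age_groups = []
        g = first
        while g.midpoint <= hi:
            age_groups.append(g)
            g = AgeGroup(g.lower + 5, g.upper + 5)
    mids = np.array([g.midpoint for g in age_groups])
    ref_idx = next(
        (i for i, g in enumerate(age_groups) if g == reference_group), None
    )

    af = np.empty((n_draws, len(age_groups)))
    n_rejected = 0
    filled = 0
    max_attempts = 1000 * n_draws
    attempts = 0
    while filled < n_draws and attempts < max_attempts:
        batch = min(n_draws - filled, n_draws)
        coefs = curve.sample_coefs(batch, rng)
        for c in coefs:
            attempts += 1
            excess = curve.predict_excess(mids, coef=c)
            eref = float(curve.predict_excess(reference_group.midpoint, coef=c)[0])
            if eref <= 0:
                n_rejected += 1
                continue
            row = excess / eref
            if ref_idx is not None:
                row[ref_idx] = 1.0
            af[filled] = row
            filled += 1
            if filled == n_draws:
                break
    if filled < n_draws:
        raise RuntimeError(
            "could not obtain enough draws with positive reference excess risk"
        )
    return AgeAttenuation(
        reference_group=reference_group,
        age_groups=list(age_groups),
        af_draws=af,
        n_rejected=n_rejected,
    )


def adjust_curve_eq1(rr_ref_draws: np.ndarray, af_draws: np.ndarray) -> np.ndarray:
    """Age-adjust risk-curve draws: RR_age = (RR_ref - 1) * AF + 1.

    ``rr_ref_draws`` is n_draws x n_doses on the RR scale; ``af_draws`` is the
    matched vector of attenuation-factor draws for one age group (draw d pairs
    with draw d, common random numbers).
    """
    rr = np.asarray(rr_ref_draws, dtype=float)
    af = np.asarray(af_draws, dtype=float)
    if rr.shape[0] != af.shape[0]:
        raise ValueError("draw counts of the risk curve and AF must match")
    return (rr - 1.0) * af[:, None] + 1.0
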