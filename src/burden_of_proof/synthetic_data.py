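"""Synthetic observation tables with known ground truth.

The generator emulates the statistical structure the dose-response pipeline
assumes: studies reporting RRs over heterogeneous exposure categories against
a zero (or occasionally ranged) reference group, log-scale sampling noise at
the reported standard error, study random intercepts and random slopes on the
true signal (between-study heterogeneity), bias-covariate shifts, a fraction
of gross outliers, optional small-study censoring, binary-exposure studies and
age-group-specific RRs for the CVD age model.  Everything is driven by one
seed, so datasets are byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .data_model import (
    ExposureInterval,
    PairConfig,
    RiskObservation,
    ValidationError,
    impute_open_upper,
    observations_to_frame,
)

CURVE_FAMILIES = ("log_linear", "log_quadratic_saturating", "sigmoid")
CENSORING_RULES = ("none", "drop_nonsignificant_high_se")


@dataclass
class TruthSpec:
    """Ground-truth configuration for one synthetic risk-outcome dataset."""

    curve_family: str = "log_linear"
    curve_params: dict = field(default_factory=lambda: {"slope": 0.04})
    gamma: float = 0.01          # between-study random-slope variance
    tau2: float = 0.01           # random-intercept variance
    bias_effects: dict = field(default_factory=dict)
    censoring: str = "none"
    outlier_fraction: float = 0.10
    n_studies: int = 30
    obs_per_study: int = 4
    exposure_measure: str = "pack_years"
    direction: str = "harmful"
    seed: int = 0
    se_range: tuple[float, float] = (0.05, 0.5)   # log-uniform reported SE
    noise_scale: float = 1.0     # multiplies the sampling noise (0 = noiseless)
    open_top_prob: float = 0.15  # chance the study's top category is open-ended
    ranged_ref_prob: float = 0.10  # chance the reference group is a low-dose range
    with_ages: bool = False

    def __post_init__(self) -> None:
        if self.curve_family not in CURVE_FAMILIES:
            raise ValidationError(f"unknown curve family {self.curve_family!r}")
        if self.censoring not in CENSORING_RULES:
            raise ValidationError(f"unknown censoring rule {self.censoring!r}")
        if not (0 <= self.outlier_fraction < 0.3):
            raise ValidationError("outlier_fraction must lie in [0, 0.3)")
        if self.gamma < 0 or self.tau2 < 0:
            raise ValidationError("variance components must be nonnegative")
        if self.obs_per_study < 1 or self.n_studies < 1:
            raise ValidationError("need at least one study and one observation per study")

    def signal(self) -> Callable[[np.ndarray], np.ndarray]:
        """The true log-RR curve s(x), anchored at s(0) = 0."""
        sign = 1.0 if self.direction == "harmful" else -1.0
        p = self.curve_params
        if self.curve_family == "log_linear":
            slope = p["slope"]
            return lambda x: sign * slope * np.asarray(x, dtype=float)
        if self.curve_family == "log_quadratic_saturating":
            slope, sat = p["slope"], p.get("saturation", 50.0)
            def f(x):
                x = np.asarray(x, dtype=float)
                rising = slope * (x - x**2 / (2 * sat))
                return sign * np.where(x < sat, rising, slope * sat / 2.0)
            return f
        amp, mid, width = p.get("amplitude", 1.0), p.get("midpoint", 20.0), p.get("width", 8.0)
        s0 = 1.0 / (1.0 + math.exp(mid / width))
        def f(x):
            x = np.asarray(x, dtype=float)
            return sign * amp * (1.0 / (1.0 + np.exp(-(x - mid) / width)) - s0) / (1.0 - s0)
        return f


def _interval_mean(fn, itv: ExposureInterval) -> float:
    if itv.is_point:
        return float(fn(itv.lower))
    val, _ = quad(lambda t: float(fn(t)), itv.lower, itv.upper, limit=200)
    return val / itv.width


def _study_intervals(
    rng: np.random.Generator, spec: TruthSpec
) -> tuple[list[ExposureInterval], ExposureInterval]:
    """Exposure categories for one study plus its reference interval."""
    study_max = float(np.clip(rng.gamma(2.0, 25.0), 10.0, 100.0))
    raw = np.sort(rng.uniform(0.15, 1.0, size=spec.obs_per_study))
    edges = raw * study_max
    lowers = np.r_[1.0, edges[:-1]]
    intervals = [
        ExposureInterval(float(lo), float(hi)) for lo, hi in zip(lowers, edges)
    ]
    if rng.uniform() < spec.open_top_prob:
        top = intervals[-1]
        widths = [iv.width for iv in intervals[:-1]]
        typical = float(np.median(widths)) if widths else None
        intervals[-1] = ExposureInterval(
            top.lower, impute_open_upper(top.lower, typical), open_ended=True
        )
    if rng.uniform() < spec.ranged_ref_prob:
        ref = ExposureInterval(0.0, float(lowers[0]))
    else:
        ref = ExposureInterval(0.0, 0.0)
    return intervals, ref


def generate_pair_dataset(spec: TruthSpec) -> tuple[pd.DataFrame, dict]:
    """Generate one observation table plus its ground-truth record.

    The truth record carries the signal function, the per-row noiseless log-RR,
    the study random effects and the planted outlier rows, so recovery can be
    scored exactly.
    """
    rng = np.random.default_rng(spec.seed)
    fn = spec.signal()
    observations: list[RiskObservation] = []
    true_log_rr: list[float] = []
    study_effects: dict[str, tuple[float, float]] = {}
    bias_names = sorted(spec.bias_effects)
    study_bias: dict[str, dict[str, float]] = {}

    for j in range(spec.n_studies):
        sid = f"study_{j:03d}"
        u_j = rng.normal(0.0, math.sqrt(spec.tau2)) if spec.tau2 > 0 else 0.0
        v_j = rng.normal(0.0, math.sqrt(spec.gamma)) if spec.gamma > 0 else 0.0
        study_effects[sid] = (u_j, v_j)
        z_j = {name: float(rng.uniform() < 0.5) for name in bias_names}
        study_bias[sid] = z_j
        design = "prospective_cohort" if rng.uniform() < 0.7 else "case_control"
        if spec.with_ages:
            base_age = float(rng.uniform(40, 70))
            age_lo, age_hi = base_age - 5.0, base_age + 5.0
            followup = float(rng.uniform(2, 15)) if design == "prospective_cohort" else None
        else:
            age_lo = age_hi = followup = None

        if spec.exposure_measure == "binary":
            intervals = [ExposureInterval(1.0, 1.0)] * spec.obs_per_study
            ref = ExposureInterval(0.0, 0.0)
        else:
            intervals, ref = _study_intervals(rng, spec)

        for alt in intervals:
            if spec.exposure_measure == "binary":
                s_true = float(fn(1.0))
            else:
                s_true = _interval_mean(fn, alt) - _interval_mean(fn, ref)
            bias_shift = sum(
                spec.bias_effects[name] * z_j[name] * s_true for name in bias_names
            )
            se = float(np.exp(rng.uniform(*np.log(spec.se_range))))
            y = s_true * (1.0 + v_j) + u_j + bias_shift + spec.noise_scale * rng.normal(0.0, se)
            observations.append(
                RiskObservation(
                    study_id=sid,
                    effect=float(np.exp(y)),
                    se_log=se,
                    ci_lower=float(np.exp(y - 1.959964 * se)),
                    ci_upper=float(np.exp(y + 1.959964 * se)),
                    alt=alt,
                    ref=ref,
                    design=design,
                    bias={name: z_j[name] for name in bias_names},
                    age_lower=age_lo,
                    age_upper=age_hi,
                    followup_years=followup,
                    followup_type="mean" if followup is not None else None,
                )
            )
            true_log_rr.append(s_true)

    n = len(observations)
    outlier_rows: list[int] = []
    n_out = int(math.floor(spec.outlier_fraction * n))
    if n_out > 0:
        outlier_rows = sorted(rng.choice(n, size=n_out, replace=False).tolist())
        for i in outlier_rows:
            obs = observations[i]
            shift = float(rng.choice([-1.0, 1.0]) * rng.uniform(3.0, 6.0) * obs.se_log)
            y = obs.log_effect + shift
            observations[i] = RiskObservation(
                study_id=obs.study_id,
                effect=float(np.exp(y)),
                se_log=obs.se_log,
                ci_lower=float(np.exp(y - 1.959964 * obs.se_log)),
                ci_upper=float(np.exp(y + 1.959964 * obs.se_log)),
                alt=obs.alt,
                ref=obs.ref,
                design=obs.design,
                bias=dict(obs.bias),
                age_lower=obs.age_lower,
                age_upper=obs.age_upper,
                followup_years=obs.followup_years,
                followup_type=obs.followup_type,
            )

    kept = np.ones(n, dtype=bool)
    if spec.censoring == "drop_nonsignificant_high_se":
        ses = np.array([o.se_log for o in observations])
        cutoff = np.quantile(ses, 2.0 / 3.0)
        for i, o in enumerate(observations):
            nonsignificant = abs(o.log_effect) < 1.959964 * o.se_log
            if nonsignificant and ses[i] > cutoff:
                kept[i] = False

    frame = observations_to_frame([o for i, o in enumerate(observations) if kept[i]])
    truth = {
        "spec": asdict(spec),
        "signal": fn,
        "true_log_rr": [v for i, v in enumerate(true_log_rr) if kept[i]],
        "study_effects": study_effects,
        "study_bias": study_bias,
        "outlier_rows": [int(np.sum(kept[: i + 1]) - 1) for i in outlier_rows if kept[i]],
        "n_censored": int(n - kept.sum()),
    }
    return frame, truth


def default_pair_config(spec: TruthSpec, **overrides) -> PairConfig:
    """PairConfig matching a TruthSpec's exposure measure and direction."""
    kwargs = dict(
        outcome_name="synthetic",
        exposure_measure=spec.exposure_measure,
        direction=spec.direction,
        monotone="nondecreasing" if spec.direction == "harmful" else "nonincreasing",
        seed=spec.seed,
    )
    kwargs.update(overrides)
    return PairConfig(**kwargs)


# ---------------------------------------------------------------------------
# age-specific binary-smoking datasets (CVD age model inputs)
# ---------------------------------------------------------------------------


@dataclass
class AgePatternSpec:
    """Ground truth for age-group-specific binary-smoking RRs.

    Excess risk declines linearly with age:
    excess(age) = base_excess * (1 + attenuation_slope * (age - reference_age)),
    floored at a small positive value.  Studies carry random slopes on age and
    report one exposure definition whose multiplicative shift on excess risk is
    a bias covariate in the age model.
    """

    n_studies: int = 20
    age_lowers: tuple[int, ...] = (40, 45, 50, 55, 60, 65, 70, 75, 80)
    base_excess: float = 1.0
    reference_age: float = 57.5
    attenuation_slope: float = -0.025   # per year: halves over 20 years
    min_excess: float = 0.05
    sd_study_slope: float = 0.005       # SD of study random slope on age (per year)
    noise_sd: float = 0.10              # natural-scale SE of excess risk
    definition_effects: dict = field(
        default_factory=lambda: {"current": 1.0, "former": 0.6, "ever": 0.8}
    )
    seed: int = 0

    def excess(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        val = self.base_excess * (1.0 + self.attenuation_slope * (age - self.reference_age))
        return np.maximum(val, self.min_excess)


def generate_age_dataset(spec: AgePatternSpec) -> tuple[pd.DataFrame, dict]:
    """Generate age-group-specific binary RRs with a known attenuation pattern."""
    if len(spec.age_lowers) < 3:
        raise ValidationError("need at least 3 age groups")
    rng = np.random.default_rng(spec.seed)
    defs = list(spec.definition_effects)
    rows = []
    for j in range(spec.n_studies):
        sid = f"age_study_{j:03d}"
        slope_j = rng.normal(0.0, spec.sd_study_slope)
        definition = defs[int(rng.integers(len(defs)))]
        mult = spec.definition_effects[definition]
        for lo in spec.age_lowers:
            mid = lo + 2.5
            e_true = float(spec.excess(mid)) * mult + slope_j * (mid - spec.reference_age)
            se_nat = spec.noise_sd * float(np.exp(rng.uniform(-0.5, 0.5))) if spec.noise_sd > 0 else 0.0
            e_obs = e_true + (rng.normal(0.0, se_nat) if se_nat > 0 else 0.0)
            rr = max(1.0 + e_obs, 0.05)
            se_log = max(se_nat, 1e-6) / rr
            rows.append(
                {
                    "study_id": sid,
                    "effect": rr,
                    "ci_lower": rr * math.exp(-1.959964 * se_log),
                    "ci_upper": rr * math.exp(1.959964 * se_log),
                    "se_log": se_log,
                    "age_lower": lo,
                    "age_upper": lo + 4,
                    "exposure_definition": definition,
                    "design": "cross_sectional",
                }
            )
    frame = pd.DataFrame(rows)
    mids = np.array([lo + 2.5 for lo in spec.age_lowers])
    truth = {
        "spec": asdict(spec),
        "true_af": (spec.excess(mids) / spec.excess(spec.reference_age)).tolist(),
        "age_midpoints": mids.tolist(),
    }
    return frame, truth
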