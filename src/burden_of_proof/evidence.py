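"""Risk-curve draws, burden-of-proof risk function, ROS and star ratings.

The fitted signal s(x) and the mixed-effects slope beta induce a distribution
of risk curves log RR(x) = beta_d * s(x), beta_d ~ N(beta_hat, var_beta +
gamma*), where gamma* is the heterogeneity variance inflated for its own
estimation uncertainty.  From the draws come the mean risk curve and its 95%
uncertainty interval; from the quantile curve closest to the null comes the
burden-of-proof risk function (BPRF): the smallest effect at each exposure
consistent with the evidence once between-study heterogeneity is accounted
for.

The risk-outcome score (ROS) is the signed log-BPRF averaged between the 15th
and 85th percentiles of observed exposure; star ratings discretise it:
ROS < 0 -> 1 star (no evidence of association), 0-0.14 -> 2, >0.14-0.41 -> 3,
>0.41-0.62 -> 4, >0.62 -> 5.  Binary-exposure pairs halve their ROS to stay
comparable with exposure-averaged continuous pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PairConfig, RiskObservation
from .heterogeneity import HeterogeneityFit
from .signal_model import SignalModel, evaluate_signal

#: dose grid used for draws and exports: 0 to 100 in steps of 0.1
DEFAULT_GRID = np.round(np.arange(0.0, 100.05, 0.1), 1)

#: ROS thresholds for star ratings 2..5 (upper edges; > last -> 5 stars)
ROS_THRESHOLDS = (0.14, 0.41, 0.62)
#: equivalent average-increased-risk thresholds in percent
PCT_THRESHOLDS_HARMFUL = (15.0, 50.0, 85.0)
PCT_THRESHOLDS_PROTECTIVE = (13.0, 34.0, 46.0)


@dataclass
class RiskCurveSet:
    """Curve draws with their pointwise mean and 95% uncertainty interval."""

    grid: np.ndarray
    mean_log_rr: np.ndarray
    ui_lower: np.ndarray
    ui_upper: np.ndarray
    draws: np.ndarray

    def mean_rr(self, dose: float) -> tuple[float, float, float]:
        """(mean RR, lower, upper) at a dose, linearly interpolated on the grid."""
        m = float(np.interp(dose, self.grid, self.mean_log_rr))
        lo = float(np.interp(dose, self.grid, self.ui_lower))
        hi = float(np.interp(dose, self.grid, self.ui_upper))
        return math.exp(m), math.exp(lo), math.exp(hi)


@dataclass
class EvidenceScore:
    """BPRF summary for one risk-outcome pair."""

    bprf_log: np.ndarray
    ros: float
    average_bprf: float
    average_increased_risk_pct: float
    stars: int
    exposure_p15: float
    exposure_p85: float
    is_binary: bool = False


def draw_curves(
    signal: SignalModel | np.ndarray,
    het: HeterogeneityFit,
    config: PairConfig,
    rng: np.random.Generator | None = None,
    grid: np.ndarray | None = None,
) -> RiskCurveSet:
    """Sample risk-curve draws log RR_d(x) = beta_d * s(x).

    beta_d ~ N(beta_hat, var_beta + gamma*); the mean curve is the draw mean
    and the 95% UI the 2.5/97.5 draw percentiles, heterogeneity-inclusive.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if grid is None:
        grid = DEFAULT_GRID
    s_grid = (
        evaluate_signal(signal, grid) if isinstance(signal, SignalModel) else np.asarray(signal)
    )
    sigma = math.sqrt(het.var_beta + het.gamma_star)
    beta_d = rng.normal(het.beta_hat, sigma, size=config.n_draws)
    draws = beta_d[:, None] * s_grid[None, :]
    return RiskCurveSet(
        grid=np.asarray(grid, dtype=float),
        mean_log_rr=draws.mean(axis=0),
        ui_lower=np.quantile(draws, 0.025, axis=0),
        ui_upper=np.quantile(draws, 0.975, axis=0),
        draws=draws,
    )


def bprf_quantile(het: HeterogeneityFit) -> float:
    """The 5% quantile of the slope distribution N(beta_hat, var_beta + gamma*).

    Multiplying the signal by this quantile yields the quantile curve closest
    to the null for harmful (nondecreasing) pairs, and — because a protective
    signal is nonpositive — also the closest-to-null (95th) curve for
    protective pairs.
    """
    sigma = math.sqrt(het.var_beta + het.gamma_star)
    return float(stats.norm.ppf(0.05, loc=het.beta_hat, scale=sigma))


def compute_bprf(
    signal: SignalModel | np.ndarray,
    het: HeterogeneityFit,
    direction: str = "harmful",
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Burden-of-proof risk function on the dose grid (log scale)."""
    if grid is None:
        grid = DEFAULT_GRID
    s_grid = (
        evaluate_signal(signal, grid) if isinstance(signal, SignalModel) else np.asarray(signal)
    )
    return bprf_quantile(het) * s_grid


def exposure_percentiles(
    observations: Sequence[RiskObservation],
    trimmed_ids: frozenset[int] | set[int] = frozenset(),
) -> tuple[float, float]:
    """15th/85th percentiles of alternative-interval midpoints (untrimmed rows).

    Linear interpolation between order statistics, unweighted.
    """
    mids = [
        o.alt.midpoint for i, o in enumerate(observations) if i not in trimmed_ids
    ]
    if not mids:
        raise ValueError("no untrimmed observations")
    p15, p85 = np.percentile(mids, [15, 85])
    return float(p15), float(p85)


def compute_ros(
    bprf_log: np.ndarray,
    grid: np.ndarray,
    p15: float,
    p85: float,
    direction: str = "harmful",
) -> float:
    """Signed log-BPRF averaged over the observed-exposure window [p15, p85].

    The average is a composite trapezoid rule over the grid points inside the
    window, with the exact window endpoints added by linear interpolation; a
    degenerate window reduces to point evaluation.
    """
    if p15 > p85:
        raise ValueError("p15 must not exceed p85")
    grid = np.asarray(grid, dtype=float)
    bprf_log = np.asarray(bprf_log, dtype=float)
    if not (grid.min() <= p15 and p85 <= grid.max()):
        raise ValueError("exposure window does not intersect the dose grid")
    if p85 == p15:
        avg = float(np.interp(p15, grid, bprf_log))
    else:
        inner = (grid > p15) & (grid < p85)
        xs = np.r_[p15, grid[inner], p85]
        ys = np.r_[
            np.interp(p15, grid, bprf_log), bprf_log[inner], np.interp(p85, grid, bprf_log)
        ]
        avg = float(np.trapezoid(ys, xs) / (p85 - p15))
    return avg if direction == "harmful" else -avg


def star_rating(ros: float) -> int:
    """Map an ROS to the 1-5 star evidence grade."""
    if not np.isfinite(ros):
        raise ValueError("ROS must be finite")
    if ros < 0:
        return 1
    for star, upper in enumerate(ROS_THRESHOLDS, start=2):
        if ros <= upper:
            return star
    return 5


def binary_ros(log_bprf_binary: float, direction: str = "harmful") -> float:
    """ROS of a binary-exposure pair: signed log-BPRF halved for comparability."""
    signed = log_bprf_binary if direction == "harmful" else -log_bprf_binary
    return signed / 2.0


def summarize_pair(
    observations: Sequence[RiskObservation],
    signal: SignalModel,
    het: HeterogeneityFit,
    config: PairConfig,
    rng: np.random.Generator | None = None,
) -> tuple[EvidenceScore, RiskCurveSet]:
    """Assemble curve draws and the evidence score for a fitted pair."""
    curves = draw_curves(signal, het, config, rng=rng)
    bprf = compute_bprf(signal, het, config.direction, grid=curves.grid)
    if config.is_binary:
        p15 = p85 = 1.0
        q = bprf_quantile(het)
        s_binary = float(signal.design_values(list(observations)[:1])[0]) if observations else 1.0
        ros = binary_ros(q * s_binary, config.direction)
    else:
        p15, p85 = exposure_percentiles(observations, signal.trimmed_ids)
        ros = compute_ros(bprf, curves.grid, p15, p85, config.direction)
    avg_bprf = math.exp(ros) if config.direction == "harmful" else math.exp(-ros)
    pct = (
        (avg_bprf - 1.0) * 100.0
        if config.direction == "harmful"
        else (1.0 - avg_bprf) * 100.0
    )
    score = EvidenceScore(
        bprf_log=bprf,
        ros=ros,
        average_bprf=avg_bprf,
        average_increased_risk_pct=pct,
        stars=star_rating(ros),
        exposure_p15=p15,
        exposure_p85=p85,
        is_binary=config.is_binary,
    )
    return score, curves


def risk_at_doses(
    curves: RiskCurveSet, doses: Sequence[float], ndigits: int = 2
) -> pd.DataFrame:
    """Mean RR with UI at selected doses (summary-table formatting, 2 decimals)."""
    rows = []
    for d in doses:
        rr, lo, hi = curves.mean_rr(d)
        rows.append(
            {
                "dose": round(float(d), ndigits),
                "mean_rr": round(rr, ndigits),
                "ui_lower": round(lo, ndigits),
                "ui_upper": round(hi, ndigits),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published-summary reclassification (printed ROS / increased-risk columns)
# ---------------------------------------------------------------------------


def load_reference_summary() -> pd.DataFrame:
    """The published per-outcome summary table (ROS, average BPRF, stars)."""
    with resources.files("burden_of_proof").joinpath(
        "data/smoking_outcome_summary.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def _star_from_pct(pct: float, direction: str) -> int:
    thresholds = (
        PCT_THRESHOLDS_HARMFUL if direction == "harmful" else PCT_THRESHOLDS_PROTECTIVE
    )
    mag = abs(pct)
    for star, upper in enumerate(thresholds, start=2):
        if mag <= upper:
            return star
    return 5


def classify_summary_rows(summary: pd.DataFrame) -> pd.Series:
    """Star-rate published summary rows from their printed ROS.

    Printed ROS values carry two decimals, so a value landing exactly on a star
    threshold is ambiguous; in that case the finer-grained average increased
    risk column decides via the equivalent percent thresholds.
    """
    stars = []
    boundaries = (0.0,) + ROS_THRESHOLDS
    for _, row in summary.iterrows():
        ros = float(row["ros"])
        pct = row.get("average_increased_risk_pct")
        on_boundary = any(abs(ros - b) < 1e-9 for b in boundaries)
        if on_boundary and pct is not None and np.isfinite(pct):
            stars.append(_star_from_pct(float(pct), str(row["direction"])))
        else:
            stars.append(star_rating(ros))
    return pd.Series(stars, index=summary.index, name="stars")


def average_bprf_from_ros(ros: float, direction: str = "harmful") -> float:
    """Exposure-averaged BPRF implied by an ROS (the exp-consistency relation)."""
    return math.exp(ros) if direction == "harmful" else math.exp(-ros)
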