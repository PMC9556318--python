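"""Publication / small-study bias diagnostics (modified funnel + Egger test).

Residuals from the fixed-effect fit are paired with a *total* standard
deviation that includes both the reported sampling error and the (inflated)
between-study heterogeneity, total_sd_i = sqrt(se_i^2 + gamma* s_i^2) — the
same quantity plotted on the y axis of the modified funnel plots.  Egger's
regression then asks whether residuals grow with total_sd: a positive slope
(for a harmful risk) means small/noisy studies report systematically larger
effects, the classic signature of publication bias.  The test flags but does
not correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PublicationBiasReport:
    """Egger slope on the heterogeneity-inclusive funnel."""

    egger_slope: float
    egger_se: float
    p_value: float
    flagged: bool
    funnel_points: list[tuple[float, float]] = field(default_factory=list)
    reason: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.funnel_points, columns=["residual", "total_sd"])


def total_sd(se_log: np.ndarray, signal_values: np.ndarray, gamma_star: float) -> np.ndarray:
    """Heterogeneity-inclusive SD per observation: sqrt(se^2 + gamma* s^2)."""
    se_log = np.asarray(se_log, dtype=float)
    s = np.asarray(signal_values, dtype=float)
    return np.sqrt(se_log**2 + gamma_star * s**2)


def egger_test(
    residuals: np.ndarray,
    total_sds: np.ndarray,
    direction: str = "harmful",
) -> PublicationBiasReport:
    """One-sided Egger regression of residuals on their total SD.

    The slope of residuals on total_sd is estimated by ordinary least squares
    (with intercept) so that the noisy small studies that carry the asymmetry
    signal are not downweighted away; its standard error uses the *known*
    per-observation variances, giving an exact-size z test.  The alternative
    is oriented by ``direction`` (positive slope for harmful risks, negative
    for protective).  Fewer than 5 points yields an unflagged report with an
    explanatory reason.
    """
    r = np.asarray(residuals, dtype=float)
    sd = np.asarray(total_sds, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("total SDs must be positive")
    points = list(zip(r.tolist(), sd.tolist()))
    if len(r) < 5:
        return PublicationBiasReport(
            egger_slope=float("nan"),
            egger_se=float("nan"),
            p_value=1.0,
            flagged=False,
            funnel_points=points,
            reason="insufficient data",
        )
    x = sd - sd.mean()
    sxx = float(np.sum(x * x))
    if sxx == 0:
        return PublicationBiasReport(
            egger_slope=0.0,
            egger_se=float("nan"),
            p_value=1.0,
            flagged=False,
            funnel_points=points,
            reason="constant total_sd",
        )
    slope = float(np.sum(x * r) / sxx)
    se = float(np.sqrt(np.sum(x * x * sd * sd)) / sxx)
    if se == 0 or not np.isfinite(se):
        p = 1.0 if slope == 0 else (0.0 if _oriented(slope, direction) > 0 else 1.0)
    else:
        p = float(stats.norm.sf(_oriented(slope, direction) / se))
    return PublicationBiasReport(
        egger_slope=slope,
        egger_se=se,
        p_value=p,
        flagged=bool(p < 0.05),
        funnel_points=points,
    )


def _oriented(slope: float, direction: str) -> float:
    return slope if direction == "harmful" else -slope
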