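"""Risk-of-bias covariate testing, Lasso selection and reference-level adjustment.

Bias covariates encode deviations of a study from the gold standard across the
six GRADE risk-of-bias domains (representativeness of the population, exposure
and outcome measurement, reverse causation, control for confounding, selection
bias) together with study-characteristic covariates such as subpopulation
sampling and the adjustment level.  A covariate at 0 means the study meets the
reference (gold-standard) level; 1 (or a higher ordinal level) means biased.

Covariates enter the metaregression as interactions with the signal, i.e. a
biased study's expected log-RR is (beta + c_k z_k) * s(x): bias rescales the
dose-response shape rather than shifting it additively.  Selection requires
both Lasso retention (penalty chosen by study-grouped cross-validation) and
significance at alpha = 0.05 in the refitted unpenalized metaregression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.linear_model import Lasso
from sklearn.model_selection import GroupKFold

from .data_model import KNOWN_BIAS_COVARIATES, PairConfig, RiskObservation, SchemaError
from .signal_model import SignalModel

logger = logging.getLogger(__name__)

ALPHA_SIG = 0.05


@dataclass
class BiasCovariateEffect:
    """Fitted effect of one bias covariate on log-RR per unit signal."""

    name: str
    coefficient: float
    selected: bool
    reference_level: float = 0.0

    @property
    def active_coefficient(self) -> float:
        """Coefficient as used in prediction: unselected covariates contribute 0."""
        return self.coefficient if self.selected else 0.0


def encode_bias_matrix(observations: Sequence[RiskObservation]) -> pd.DataFrame:
    """Observation-by-covariate matrix, 0 = reference level.

    Missing covariate entries default to the reference level (with a warning);
    unknown covariate names raise :class:`SchemaError`.
    """
    names = sorted({n for o in observations for n in o.bias})
    for name in names:
        if name not in KNOWN_BIAS_COVARIATES:
            raise SchemaError(f"unknown bias covariate {name!r}")
    data = np.zeros((len(observations), len(names)))
    n_missing = 0
    for i, obs in enumerate(observations):
        for j, name in enumerate(names):
            if name in obs.bias:
                data[i, j] = obs.bias[name]
            else:
                n_missing += 1
    if n_missing:
        logger.warning(
            "%d missing bias entries defaulted to the reference level", n_missing
        )
    return pd.DataFrame(data, columns=names)


def _grouped_lasso_cv(
    F: np.ndarray, r: np.ndarray, w: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Lasso coefficients at the study-grouped cross-validated penalty."""
    n, p = F.shape
    alpha_max = np.max(np.abs(F.T @ (w * r))) / max(w.sum(), 1.0)
    if alpha_max <= 0:
        return np.zeros(p)
    alphas = alpha_max * np.logspace(0, -3, 30)
    n_groups = len(np.unique(groups))
    n_splits = min(5, n_groups)
    if n_splits >= 2:
        cv_err = np.zeros(len(alphas))
        splitter = GroupKFold(n_splits=n_splits)
        for train, test in splitter.split(F, r, groups):
            for a_i, alpha in enumerate(alphas):
                model = Lasso(alpha=alpha, fit_intercept=False, max_iter=5000)
                model.fit(F[train], r[train], sample_weight=w[train])
                pred = model.predict(F[test])
                cv_err[a_i] += np.sum(w[test] * (r[test] - pred) ** 2)
        best = alphas[int(np.argmin(cv_err))]
    else:  # single study: no grouped CV possible, use the most conservative penalty
        best = alphas[0]
    final = Lasso(alpha=best, fit_intercept=False, max_iter=5000)
    final.fit(F, r, sample_weight=w)
    return final.coef_


def select_bias_covariates(
    observations: Sequence[RiskObservation],
    signal: SignalModel,
    config: PairConfig,
    *,
    signal_values: np.ndarray | None = None,
) -> list[BiasCovariateEffect]:
    """Test bias covariates by metaregression and select via Lasso + significance.

    The candidate model is y_i = beta * s_i + sum_k c_k z_ik s_i + noise with
    inverse-variance weights.  Covariates are standardized inside the Lasso
    path, so selection is invariant to affine rescaling of the encodings.
    Constant covariate columns are untestable and excluded with a log entry.
    """
    Z = encode_bias_matrix(observations)
    if Z.shape[1] == 0:
        return []
    n = len(observations)
    keep = np.ones(n, dtype=bool)
    if signal.trimmed_ids:
        keep[list(signal.trimmed_ids)] = False
    s = signal.design_values(observations) if signal_values is None else signal_values
    y = np.array([o.log_effect for o in observations])
    w = np.array([1.0 / o.se_log**2 for o in observations])
    groups = np.array([o.study_id for o in observations])
    s, y, w, groups = s[keep], y[keep], w[keep], groups[keep]
    Zk = Z.values[keep]

    testable, dropped = [], []
    for j, name in enumerate(Z.columns):
        if np.unique(Zk[:, j]).size < 2:
            dropped.append(name)
        else:
            testable.append(j)
    if dropped:
        logger.info("constant bias covariates excluded: %s", dropped)
    effects = [
        BiasCovariateEffect(name=name, coefficient=0.0, selected=False)
        for name in Z.columns
    ]
    if not testable:
        return effects

    # partial the common signal slope out of both response and interactions
    # (Frisch-Waugh), so the Lasso sees the covariate effect net of the shared
    # dose-response trend it is heavily collinear with
    denom = np.sum(w * s * s)
    if denom <= 0:
        return effects
    beta0 = np.sum(w * s * y) / denom
    r = y - beta0 * s
    F = Zk[:, testable] * s[:, None]
    proj = (F.T @ (w * s)) / denom
    F = F - np.outer(s, proj)
    scale = F.std(axis=0)
    scale[scale == 0] = 1.0
    Fs = F / scale
    coef = _grouped_lasso_cv(Fs, r, w, groups)
    candidates = [testable[j] for j in np.flatnonzero(np.abs(coef) > 1e-10)]
    if not candidates:
        return effects

    # refit unpenalized with the study random effects (a plain WLS refit is
    # anticonservative when between-study variance is present) and keep
    # candidates significant at alpha
    from .heterogeneity import fit_mixed_effects

    obs_kept = [o for o, k in zip(observations, keep) if k]
    interactions = np.column_stack([Zk[:, j] * s for j in candidates])
    het = fit_mixed_effects(obs_kept, s, interactions)
    cov = _fixed_cov(het)
    for pos, j in enumerate(candidates, start=1):
        eff = effects[j]
        coef = float(het.fixed_effects[pos])
        se_coef = math.sqrt(max(cov[pos, pos], 1e-300))
        p = 2.0 * float(norm.sf(abs(coef) / se_coef))
        eff.coefficient = coef
        eff.selected = bool(p < ALPHA_SIG)
    return effects


def _fixed_cov(het) -> np.ndarray:
    """Covariance of the fixed effects with heterogeneity inflated to gamma*.

    Using gamma_hat directly is anticonservative when the between-study
    variance sits at its boundary; evaluating at gamma* = gamma_hat +
    2 SD(gamma) mirrors how heterogeneity uncertainty enters the BPRF.
    """
    ctx = het.context
    return ctx.gls(het.tau2, het.gamma_star)[1]


def adjust_to_reference(
    log_rr: np.ndarray,
    signal_values: np.ndarray,
    bias_rows: np.ndarray | pd.DataFrame,
    effects: Sequence[BiasCovariateEffect],
) -> np.ndarray:
    """Remove selected-covariate contributions, i.e. predict at the reference level.

    For observation i with covariate row z_i the adjusted value is
    ``log_rr_i - sum_k c_k (z_ik - ref_k) * s_i``; a pure function that is the
    identity when nothing is selected or everything sits at reference.
    """
    log_rr = np.asarray(log_rr, dtype=float)
    s = np.asarray(signal_values, dtype=float)
    if isinstance(bias_rows, pd.DataFrame):
        cols = {name: bias_rows[name].values for name in bias_rows.columns}
    else:
        bias_rows = np.asarray(bias_rows, dtype=float)
        cols = {eff.name: bias_rows[:, k] for k, eff in enumerate(effects)}
    out = log_rr.copy()
    for eff in effects:
        if eff.selected and eff.name in cols:
            out = out - eff.active_coefficient * (cols[eff.name] - eff.reference_level) * s
    return out


def bias_report(effects: Sequence[BiasCovariateEffect]) -> dict:
    """JSON-ready summary of tested and selected bias covariates."""
    return {
        "tested": [e.name for e in effects],
        "selected": {e.name: e.coefficient for e in effects if e.selected},
    }
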