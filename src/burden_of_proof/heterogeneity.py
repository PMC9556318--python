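"""Mixed-effects metaregression on the signal and heterogeneity uncertainty.

Model for observation i in study j, with s_i the signal design value:

    y_i = beta * s_i + sum_k c_k z_ik s_i + u_j + v_j s_i + eps_i,
    u_j ~ N(0, tau2),  v_j ~ N(0, gamma),  eps_i ~ N(0, se_i^2)

The study random intercept u_j absorbs within-study correlation; the random
slope v_j on the signal is the between-study heterogeneity, with variance
gamma.  Estimation is by maximum marginal likelihood with the variance
components constrained nonnegative.  Because gamma is under-estimated (often
exactly zero) with few studies, its sampling uncertainty SD(gamma) is taken
from the Fisher information of the marginal likelihood and the inflated value
gamma* = gamma_hat + 2 * SD(gamma) is what downstream uncertainty uses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize

from .data_model import RiskObservation

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Marginal-likelihood optimisation failed to converge."""


@dataclass
class FitContext:
    """Everything needed to re-evaluate the marginal likelihood after fitting.

    Per-study covariances have the rank-2 structure V_j = D_j + U_j C U_j'
    with U_j = [1, s_j] and C = diag(tau2, gamma), so GLS quantities are
    evaluated through the Woodbury identity: all data-dependent pieces are
    cached once and only a 2x2 per-study system depends on the parameters.
    """

    y: np.ndarray
    X: np.ndarray
    s: np.ndarray
    se2: np.ndarray
    blocks: list[np.ndarray]  # row indices per study

    def __post_init__(self) -> None:
        self._groups = []  # per block-size group: cached sufficient statistics
        sizes: dict[int, list[np.ndarray]] = {}
        for idx in self.blocks:
            sizes.setdefault(len(idx), []).append(idx)
        p = self.X.shape[1]
        self._logdet_d = float(np.sum(np.log(self.se2)))
        for length, idx_list in sizes.items():
            idx = np.stack(idx_list)                       # (m, L)
            d = self.se2[idx]                              # (m, L)
            U = np.stack([np.ones_like(self.s[idx]), self.s[idx]], axis=2)  # (m, L, 2)
            Xb = self.X[idx]                               # (m, L, p)
            yb = self.y[idx]                               # (m, L)
            DU = U / d[:, :, None]
            self._groups.append(
                {
                    "M": np.einsum("mlk,mlj->mkj", U, DU),        # U' D^-1 U
                    "P": np.einsum("mlk,mlp->mkp", DU, Xb),       # U' D^-1 X
                    "q": np.einsum("mlk,ml->mk", DU, yb),         # U' D^-1 y
                    "XtDX": np.einsum("mlp,ml,mlq->pq", Xb, 1.0 / d, Xb),
                    "XtDy": np.einsum("mlp,ml,ml->p", Xb, 1.0 / d, yb),
                    "ytDy": float(np.einsum("ml,ml,ml->", yb, 1.0 / d, yb)),
                }
            )

    @staticmethod
    def _K(M: np.ndarray, tau2: float, gamma: float) -> tuple[np.ndarray, np.ndarray]:
        """C (I + M C)^-1 per study and log det(I + M C); Woodbury core."""
        a00 = 1.0 + M[:, 0, 0] * tau2
        a01 = M[:, 0, 1] * gamma
        a10 = M[:, 1, 0] * tau2
        a11 = 1.0 + M[:, 1, 1] * gamma
        det = a00 * a11 - a01 * a10
        if np.any(det <= 0):
            raise np.linalg.LinAlgError("indefinite study covariance")
        K = np.empty_like(M)
        K[:, 0, 0] = tau2 * a11 / det
        K[:, 0, 1] = -tau2 * a01 / det
        K[:, 1, 0] = -gamma * a10 / det
        K[:, 1, 1] = gamma * a00 / det
        return K, np.log(det)

    def _accumulate(self, tau2: float, gamma: float):
        p = self.X.shape[1]
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        ytWy = 0.0
        logdet = self._logdet_d
        for g in self._groups:
            K, logdet_a = self._K(g["M"], tau2, gamma)
            logdet += float(np.sum(logdet_a))
            XtWX += g["XtDX"] - np.einsum("mkp,mkj,mjq->pq", g["P"], K, g["P"])
            XtWy += g["XtDy"] - np.einsum("mkp,mkj,mj->p", g["P"], K, g["q"])
            ytWy += g["ytDy"] - float(np.einsum("mk,mkj,mj->", g["q"], K, g["q"]))
        return XtWX, XtWy, ytWy, logdet

    def nll(self, params: np.ndarray) -> float:
        """Joint negative log marginal likelihood at (fixed effects, tau2, gamma)."""
        p = self.X.shape[1]
        b, tau2, gamma = params[:p], params[p], params[p + 1]
        if tau2 < 0 or gamma < 0:
            return np.inf
        try:
            XtWX, XtWy, ytWy, logdet = self._accumulate(tau2, gamma)
        except np.linalg.LinAlgError:
            return np.inf
        quad = ytWy - 2.0 * b @ XtWy + b @ XtWX @ b
        return float(0.5 * (len(self.y) * math.log(2 * math.pi) + logdet + quad))

    def gls(self, tau2: float, gamma: float) -> tuple[np.ndarray, np.ndarray, float]:
        """Profile the fixed effects: returns (b_hat, cov_b, profiled nll)."""
        XtWX, XtWy, ytWy, logdet = self._accumulate(tau2, gamma)
        cov_b = np.linalg.inv(XtWX)
        b = cov_b @ XtWy
        nll = 0.5 * (
            len(self.y) * math.log(2 * math.pi) + logdet + ytWy - b @ XtWy
        )
        return b, cov_b, float(nll)

    def study_quadratics(self, tau2: float, gamma: float) -> np.ndarray:
        """Per-study (1'W1, 1'Ws, s'Ws) as an (n_studies, 3) array."""
        rows = []
        for g in self._groups:
            K, _ = self._K(g["M"], tau2, gamma)
            UWU = g["M"] - np.einsum("mkj,mjl,mli->mki", g["M"], K, g["M"])
            rows.append(np.stack([UWU[:, 0, 0], UWU[:, 0, 1], UWU[:, 1, 1]], axis=1))
        return np.concatenate(rows, axis=0)


@dataclass
class HeterogeneityFit:
    """Fixed-effect slope on the signal with between-study variance estimates."""

    beta_hat: float
    var_beta: float
    gamma_hat: float
    sd_gamma: float
    tau2: float
    loglik: float
    n_studies: int
    n_obs: int
    fixed_effects: np.ndarray = field(default_factory=lambda: np.zeros(1))
    context: FitContext | None = None
    random_intercept: bool = True
    random_slope: bool = True

    def __post_init__(self) -> None:
        if self.gamma_hat < 0 or self.sd_gamma < 0 or self.var_beta <= 0:
            raise ValueError("variance estimates must be nonnegative (var_beta > 0)")

    @property
    def gamma_star(self) -> float:
        """Heterogeneity inflated for its own estimation uncertainty."""
        return self.gamma_hat + 2.0 * self.sd_gamma

    def summary(self) -> dict:
        return {
            "beta_hat": self.beta_hat,
            "var_beta": self.var_beta,
            "gamma_hat": self.gamma_hat,
            "sd_gamma": self.sd_gamma,
            "gamma_star": self.gamma_star,
            "tau2": self.tau2,
            "n_studies": self.n_studies,
            "n_obs": self.n_obs,
            "loglik": self.loglik,
        }


def _make_context(
    observations: Sequence[RiskObservation],
    signal_values: np.ndarray,
    bias_interactions: np.ndarray | None,
) -> FitContext:
    y = np.array([o.log_effect for o in observations])
    se2 = np.array([o.se_log**2 for o in observations])
    s = np.asarray(signal_values, dtype=float)
    cols = [s]
    if bias_interactions is not None and bias_interactions.size:
        cols.extend(np.asarray(bias_interactions, dtype=float).T)
    X = np.column_stack(cols)
    studies = np.array([o.study_id for o in observations])
    blocks = [np.flatnonzero(studies == sid) for sid in pd_unique(studies)]
    return FitContext(y=y, X=X, s=s, se2=se2, blocks=blocks)


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Order-preserving unique (keeps study blocks in input order)."""
    _, first = np.unique(values, return_index=True)
    return values[np.sort(first)]


def fit_variance_components(
    ctx: FitContext,
    *,
    n_restarts: int = 4,
    random_intercept: bool = True,
    random_slope: bool = True,
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Maximise the marginal likelihood over (tau2, gamma) with profiled fixed effects.

    Either variance component can be fixed at zero — e.g. the intercept when
    the signal is constant within studies (where the two are confounded), or
    the slope for a gamma-free fixed-effect-style fit.  Returns
    (b_hat, cov_b, tau2_hat, gamma_hat, nll at optimum).
    """
    med_se2 = float(np.median(ctx.se2))
    s_scale = max(float(np.mean(ctx.s**2)), 1e-8)
    starts = [
        (0.0, 0.0),
        (med_se2, med_se2 / s_scale),
        (0.1 * med_se2, 0.01),
        (med_se2, 0.0),
    ][: max(1, n_restarts)]
    free = [random_intercept, random_slope]
    if not any(free):
        b, cov_b, nll = ctx.gls(0.0, 0.0)
        return b, cov_b, 0.0, 0.0, nll

    def expand(theta: np.ndarray) -> tuple[float, float]:
        it = iter(theta)
        return (
            float(next(it)) if random_intercept else 0.0,
            float(next(it)) if random_slope else 0.0,
        )

    def objective(theta: np.ndarray) -> float:
        tau2, gamma = expand(theta)
        try:
            return ctx.gls(tau2, gamma)[2]
        except np.linalg.LinAlgError:
            return np.inf

    best = None
    for start in starts:
        x0 = np.array([v for v, f in zip(start, free) if f])
        res = minimize(
            objective,
            x0=x0,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * len(x0),
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("marginal likelihood optimisation failed")
    tau2, gamma = expand(best.x)
    b, cov_b, nll = ctx.gls(tau2, gamma)
    return b, cov_b, tau2, gamma, nll


def fit_mixed_effects(
    observations: Sequence[RiskObservation],
    signal_values: np.ndarray,
    bias_interactions: np.ndarray | None = None,
    *,
    n_restarts: int = 4,
    random_intercept: bool = True,
    random_slope: bool = True,
) -> HeterogeneityFit:
    """Maximum marginal likelihood fit of the random intercept + slope model.

    ``bias_interactions`` are extra fixed-effect columns (z_ik * s_i for the
    selected bias covariates).  ``random_intercept=False`` drops the study
    intercept (tau2 = 0), e.g. for designs where the slope covariate is
    constant within studies and the two components are confounded.  With a
    single study the variance components are not identifiable and are fixed to
    zero with a warning.
    """
    ctx = _make_context(observations, signal_values, bias_interactions)
    if np.allclose(ctx.s, 0):
        raise ValueError("signal values are all zero; the slope is unidentifiable")
    n_studies = len(ctx.blocks)
    if n_studies < 2:
        logger.warning("single study: between-study variances fixed to 0")
        b, cov_b, nll = ctx.gls(0.0, 0.0)
        return HeterogeneityFit(
            beta_hat=float(b[0]),
            var_beta=float(cov_b[0, 0]),
            gamma_hat=0.0,
            sd_gamma=0.0,
            tau2=0.0,
            loglik=-nll,
            n_studies=n_studies,
            n_obs=len(ctx.y),
            fixed_effects=b,
            context=ctx,
        )

    b, cov_b, tau2, gamma, nll = fit_variance_components(
        ctx,
        n_restarts=n_restarts,
        random_intercept=random_intercept,
        random_slope=random_slope,
    )
    fit = HeterogeneityFit(
        beta_hat=float(b[0]),
        var_beta=float(cov_b[0, 0]),
        gamma_hat=gamma,
        sd_gamma=0.0,
        tau2=tau2,
        loglik=-nll,
        n_studies=n_studies,
        n_obs=len(ctx.y),
        fixed_effects=b,
        context=ctx,
        random_intercept=random_intercept,
        random_slope=random_slope,
    )
    fit.sd_gamma = fisher_sd_gamma(fit) if random_slope else 0.0
    return fit


def variance_component_information(
    ctx: FitContext, tau2: float, gamma: float
) -> np.ndarray:
    """Expected Fisher information of (tau2, gamma) under the marginal model.

    With V_j the per-study covariance and W_j its inverse, dV/dtau2 = 11' and
    dV/dgamma = s s', so the 2x2 information has the closed form

        I = 0.5 * sum_j [ (1'W1)^2      (1'W s)^2 ;
                          (1'W s)^2     (s'W s)^2 ].

    It is positive semidefinite by construction, remains well defined at the
    gamma = 0 boundary, and (mean and variance parameters being orthogonal in
    Gaussian models) its inverse is the (tau2, gamma) block of the inverse
    full-parameter information.
    """
    quads = ctx.study_quadratics(tau2, gamma)
    a, b, c = quads[:, 0], quads[:, 1], quads[:, 2]
    return 0.5 * np.array(
        [[np.sum(a * a), np.sum(b * b)], [np.sum(b * b), np.sum(c * c)]]
    )


def fisher_sd_gamma(fit: HeterogeneityFit) -> float:
    """SD of gamma_hat from the Fisher information of the marginal likelihood.

    sd_gamma is the square root of the (gamma, gamma) entry of the inverse
    information evaluated at the optimum.  The expected information is used
    because it stays positive semidefinite when gamma_hat sits at its zero
    boundary (where the observed curvature can be negative); when the
    information matrix is singular — e.g. the signal is constant within
    studies, confounding tau2 and gamma — the width of the half-unit
    profile-likelihood step is used instead, with a log entry.
    """
    ctx = fit.context
    if ctx is None:
        raise ValueError("fit carries no context; refit with fit_mixed_effects")
    info = variance_component_information(ctx, fit.tau2, fit.gamma_hat)
    if not fit.random_intercept:
        if info[1, 1] > 0:
            return math.sqrt(1.0 / info[1, 1])
    else:
        det = np.linalg.det(info)
        if det > 1e-8 * max(info[0, 0] * info[1, 1], 1e-300):
            var_gamma = float(np.linalg.inv(info)[1, 1])
            if var_gamma > 0:
                return math.sqrt(var_gamma)
    logger.warning("singular information matrix; using profile-likelihood width")
    return _profile_width(ctx, fit)


def _profile_width(ctx: FitContext, fit: HeterogeneityFit) -> float:
    """Width of the half-unit profile-likelihood step in gamma (one-sided)."""
    nll_min = ctx.gls(fit.tau2, fit.gamma_hat)[2]

    def g(gamma: float) -> float:
        if not fit.random_intercept:
            return ctx.gls(0.0, gamma)[2] - nll_min - 0.5
        res = minimize(
            lambda t: ctx.gls(t[0], gamma)[2],
            x0=np.array([fit.tau2]),
            method="L-BFGS-B",
            bounds=[(0.0, None)],
        )
        return res.fun - nll_min - 0.5

    hi = max(fit.gamma_hat, 1e-4)
    for _ in range(60):
        if g(fit.gamma_hat + hi) > 0:
            break
        hi *= 2
    else:  # pragma: no cover - likelihood flat in gamma
        return hi
    return brentq(g, fit.gamma_hat, fit.gamma_hat + hi) - fit.gamma_hat


def fixed_effect_residuals(fit: HeterogeneityFit) -> np.ndarray:
    """Residuals against the fixed-effect prediction (random effects not removed)."""
    ctx = fit.context
    if ctx is None:
        raise ValueError("fit carries no context; refit with fit_mixed_effects")
    return ctx.y - ctx.X @ fit.fixed_effects
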