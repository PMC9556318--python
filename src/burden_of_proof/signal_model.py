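"""Ensemble-spline estimation of the log-relative-risk shape ("signal").

The dose-response shape s(x) of log(RR) against exposure is estimated by a
weighted ensemble of cubic splines with randomly placed interior knots.  Each
member is fitted by inverse-variance weighted least squares to *ranged*
observations: an observation constrains the difference between the average of
s over its alternative exposure interval and the average over its reference
interval, which is how risk estimates reported across heterogeneous exposure
categories are made comparable.

Monotone shape constraints are imposed by construction: s is parameterised
through its derivative expanded in a quadratic B-spline basis, so nonnegative
(nonpositive) basis weights give a nondecreasing (nonincreasing) cubic spline
with s(0) = 0 exactly.  Robustness to gross outliers comes from trimming a
fixed fraction of observations with the largest standardized residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import nnls

from .data_model import ExposureInterval, PairConfig, RiskObservation

#: penalty weight on the total variation of s' in the ensemble weighting
LAMBDA_TV = 0.1

_DERIV_DEGREE = 2  # derivative basis degree; the fitted spline is cubic


class FittingError(RuntimeError):
    """Spline fitting failed (infeasible/underdetermined system)."""


def _deriv_knot_vector(knots: np.ndarray) -> np.ndarray:
    """Clamped knot vector for the quadratic derivative basis."""
    k = _DERIV_DEGREE
    return np.r_[[knots[0]] * (k + 1), knots[1:-1], [knots[-1]] * (k + 1)]


def _n_basis(knots: np.ndarray) -> int:
    return len(_deriv_knot_vector(knots)) - _DERIV_DEGREE - 1


@dataclass
class SplineMember:
    """One ensemble member: a monotone-constrained cubic spline for s(x).

    ``coefficients`` are weights on the integrated quadratic B-spline basis
    (the derivative of s), so the shape constraint is simply a sign constraint.
    """

    knots: np.ndarray
    degree: int
    coefficients: np.ndarray
    fit_score: float = float("nan")
    total_variation: float = float("nan")
    trimmed_ids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.knots[0] != 0:
            raise ValueError("first knot must be 0 (zero-exposure anchor)")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        t = _deriv_knot_vector(self.knots)
        self._dspline = BSpline(t, self.coefficients, _DERIV_DEGREE, extrapolate=True)
        self._spline = self._dspline.antiderivative()  # s, with s(0)=0
        self._ispline = self._spline.antiderivative()

    @property
    def xmax(self) -> float:
        return float(self.knots[-1])

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        return self._dspline(np.clip(x, 0.0, self.xmax))

    def evaluate(self, x):
        """s(x); linear continuation at the boundary slope beyond the last knot."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("exposure must be nonnegative")
        inside = np.minimum(x, self.xmax)
        out = self._spline(inside)
        tail = x > self.xmax
        if np.any(tail):
            slope = float(self._dspline(self.xmax))
            out = np.where(tail, self._spline(self.xmax) + slope * (x - self.xmax), out)
        return out if out.ndim else float(out)

    def integral(self, a: float, b: float) -> float:
        """Exact integral of s over [a, b] (linear-tail beyond the last knot)."""
        if a > b:
            raise ValueError("integration bounds out of order")
        xm = self.xmax
        lo, hi = min(a, xm), min(b, xm)
        total = float(self._ispline(hi) - self._ispline(lo))
        if b > xm:
            s_end = float(self._spline(xm))
            slope = float(self._dspline(xm))
            ta, tb = max(a, xm) - xm, b - xm
            total += s_end * (tb - ta) + 0.5 * slope * (tb**2 - ta**2)
        return total

    def interval_mean(self, interval: ExposureInterval) -> float:
        """Average of s over an exposure interval (point value if degenerate)."""
        if interval.is_point:
            return float(self.evaluate(interval.lower))
        return self.integral(interval.lower, interval.upper) / interval.width


def ranged_design_value(
    member: SplineMember, alt: ExposureInterval, ref: ExposureInterval
) -> float:
    """Expected log-RR of an observation under the member's shape.

    Mean of s over the alternative interval minus the mean over the reference
    interval, with exact polynomial integration.
    """
    return member.interval_mean(alt) - member.interval_mean(ref)


def _basis_members(knots: np.ndarray) -> list[BSpline]:
    t = _deriv_knot_vector(knots)
    nb = len(t) - _DERIV_DEGREE - 1
    eye = np.eye(nb)
    return [BSpline(t, eye[k], _DERIV_DEGREE, extrapolate=True) for k in range(nb)]


def design_matrix(knots: np.ndarray, observations: Sequence[RiskObservation]) -> np.ndarray:
    """Ranged design matrix: A[i, k] = ranged value of the k-th basis element."""
    knots = np.asarray(knots, dtype=float)
    basis = _basis_members(knots)
    n, nb = len(observations), len(basis)
    alt_lo = np.array([o.alt.lower for o in observations])
    alt_up = np.array([o.alt.upper for o in observations])
    ref_lo = np.array([o.ref.lower for o in observations])
    ref_up = np.array([o.ref.upper for o in observations])
    alt_w = np.where(alt_up > alt_lo, alt_up - alt_lo, 1.0)
    ref_w = np.where(ref_up > ref_lo, ref_up - ref_lo, 1.0)
    alt_point = alt_up == alt_lo
    ref_point = ref_up == ref_lo
    A = np.empty((n, nb))
    for k, bk in enumerate(basis):
        ik = bk.antiderivative()       # basis contribution to s
        sk = ik.antiderivative()       # and its antiderivative, for interval means
        alt_val = np.where(alt_point, ik(alt_lo), (sk(alt_up) - sk(alt_lo)) / alt_w)
        ref_val = np.where(ref_point, ik(ref_lo), (sk(ref_up) - sk(ref_lo)) / ref_w)
        A[:, k] = alt_val - ref_val
    return A


def _total_variation(member: SplineMember) -> float:
    """Exact total variation of s' over the knot span (integral of |s''|)."""
    d2 = member._dspline.derivative()  # piecewise linear
    total = 0.0
    ts = np.unique(member.knots)
    for a, b in zip(ts[:-1], ts[1:]):
        v0, v1 = float(d2(a)), float(d2(b - 1e-12 * (b - a)))
        h = b - a
        if v0 * v1 >= 0:
            total += 0.5 * abs(v0 + v1) * h
        else:
            total += 0.5 * h * (v0**2 + v1**2) / (abs(v0) + abs(v1))
    return total


def _solve(Aw: np.ndarray, yw: np.ndarray, monotone: str) -> np.ndarray:
    if monotone == "nondecreasing":
        c, _ = nnls(Aw, yw)
    elif monotone == "nonincreasing":
        c, _ = nnls(Aw, -yw)
        c = -c
    else:
        c, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    return c


def fit_member(
    observations: Sequence[RiskObservation],
    knots: np.ndarray,
    config: PairConfig,
    *,
    include: np.ndarray | None = None,
    trim: bool | None = None,
    _design: np.ndarray | None = None,
) -> SplineMember:
    """Fit one spline member by trimmed, weighted, shape-constrained least squares.

    ``include`` restricts fitting to a boolean subset of rows (used when the
    ensemble shares a trimmed set); ``trim`` toggles the iterative trimming of
    the ceil(trim_fraction * n) largest absolute standardized residuals.
    """
    knots = np.asarray(knots, dtype=float)
    n = len(observations)
    A = design_matrix(knots, observations) if _design is None else _design
    y = np.array([o.log_effect for o in observations])
    w = np.array([1.0 / o.se_log for o in observations])
    if include is None:
        include = np.ones(n, dtype=bool)
    if trim is None:
        trim = config.trim_fraction > 0
    n_inc = int(include.sum())
    h = math.ceil(config.trim_fraction * n_inc) if trim else 0
    nb = A.shape[1]
    if n_inc - h < max(5, nb):
        raise FittingError(
            f"need at least max(5, {nb}) untrimmed observations, have {n_inc - h}"
        )

    inc_idx = np.flatnonzero(include)
    trimmed: np.ndarray = np.array([], dtype=int)
    c = np.zeros(nb)
    for _ in range(20):
        active = np.setdiff1d(inc_idx, trimmed, assume_unique=False)
        Aw = A[active] * w[active, None]
        yw = y[active] * w[active]
        c = _solve(Aw, yw, config.monotone)
        if h == 0:
            break
        resid = np.abs((y[inc_idx] - A[inc_idx] @ c) * w[inc_idx])
        order = np.argsort(resid, kind="stable")
        new_trimmed = np.sort(inc_idx[order[-h:]])
        if np.array_equal(new_trimmed, trimmed):
            break
        trimmed = new_trimmed

    active = np.setdiff1d(inc_idx, trimmed)
    r = (y[active] - A[active] @ c) * w[active]
    mse = max(float(np.mean(r**2)), 1e-12)
    member = SplineMember(
        knots=knots,
        degree=3,
        coefficients=c,
        trimmed_ids=frozenset(int(i) for i in trimmed),
    )
    member.fit_score = -0.5 * len(active) * math.log(mse)
    member.total_variation = _total_variation(member)
    return member


@dataclass
class SignalModel:
    """Weighted ensemble of spline members plus the shared trimmed set."""

    members: list[SplineMember]
    weights: np.ndarray
    trimmed_ids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("ensemble weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("ensemble weights must be nonnegative")

    def evaluate(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for wgt, m in zip(self.weights, self.members):
            out = out + wgt * m.evaluate(x)
        return out if out.ndim else float(out)

    def design_values(self, observations: Sequence[RiskObservation]) -> np.ndarray:
        """Ensemble ranged design value per observation (the metaregression covariate)."""
        vals = np.zeros(len(observations))
        for wgt, m in zip(self.weights, self.members):
            vals += wgt * np.array(
                [ranged_design_value(m, o.alt, o.ref) for o in observations]
            )
        return vals

    @property
    def xmax(self) -> float:
        return max(m.xmax for m in self.members)


def evaluate_signal(model: SignalModel, x) -> np.ndarray:
    """Evaluate the ensemble signal s on an exposure grid (x >= 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("exposure must be nonnegative")
    return model.evaluate(x)


def linear_member(xmax: float) -> SplineMember:
    """A unit-slope linear member, s(x) = x: derivative basis weights all one."""
    knots = np.array([0.0, xmax])
    member = SplineMember(knots=knots, degree=3, coefficients=np.ones(_n_basis(knots)))
    member.fit_score = 0.0
    member.total_variation = 0.0
    return member


def _exposure_span(observations: Sequence[RiskObservation]) -> float:
    return max(max(o.alt.upper, o.ref.upper) for o in observations)


def _random_interior_knots(
    rng: np.random.Generator, lo: float, hi: float, xmax: float
) -> np.ndarray:
    n_int = int(rng.integers(2, 5))
    min_gap = 0.01 * xmax
    for _ in range(100):
        pos = np.sort(rng.uniform(lo, hi, n_int))
        cand = np.r_[0.0, pos, xmax]
        if np.all(np.diff(cand) > min_gap):
            return pos
    return np.linspace(lo, hi, n_int + 2)[1:-1]  # deterministic fallback


def ensemble_weights(
    fit_scores: np.ndarray, total_variations: np.ndarray, lambda_tv: float = LAMBDA_TV
) -> np.ndarray:
    """Member weights: log w_j = fit_score_j - lambda_tv * TV_j, softmax-normalized.

    fit_score is -0.5 n log(MSE), so equal-MSE, equal-TV members share weight
    equally and better-fitting, less-wiggly members dominate.
    """
    scores = np.asarray(fit_scores) - lambda_tv * np.asarray(total_variations)
    scores = scores - scores.max()
    w = np.exp(scores)
    return w / w.sum()


def fit_ensemble(
    observations: Sequence[RiskObservation],
    config: PairConfig,
    rng: np.random.Generator | None = None,
    *,
    lambda_tv: float = LAMBDA_TV,
) -> SignalModel:
    """Fit the trimmed ensemble signal model.

    A pilot member with quantile-placed knots determines the trimmed set, which
    is then shared by all ensemble members (so the ensemble has one coherent
    outlier set).  Member weights combine goodness of fit and a total-variation
    penalty: log w_j = -0.5 n log(MSE_j) - lambda_tv * TV_j, normalized.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(observations)
    xmax = _exposure_span(observations)
    if xmax <= 0:
        raise FittingError("all exposure intervals are degenerate at zero")
    mids = np.array([o.alt.midpoint for o in observations])
    qlo, qhi = np.quantile(mids, [0.1, 0.9])
    if qhi - qlo < 0.05 * xmax:
        qlo, qhi = 0.1 * xmax, 0.9 * xmax

    pilot_int = np.unique(np.quantile(mids, [0.25, 0.5, 0.75]))
    pilot_int = pilot_int[(pilot_int > 0.01 * xmax) & (pilot_int < 0.99 * xmax)]
    if len(pilot_int) == 0:
        pilot_int = np.linspace(0, xmax, 5)[1:-1]
    pilot_knots = np.r_[0.0, pilot_int, xmax]
    pilot = fit_member(observations, pilot_knots, config)
    trimmed = pilot.trimmed_ids
    include = np.ones(n, dtype=bool)
    include[list(trimmed)] = False

    members: list[SplineMember] = []
    errors: list[str] = []
    for _ in range(config.n_ensemble):
        interior = _random_interior_knots(rng, qlo, qhi, xmax)
        knots = np.r_[0.0, interior, xmax]
        try:
            members.append(
                fit_member(observations, knots, config, include=include, trim=False)
            )
        except (FittingError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            errors.append(str(exc))
    if not members:
        raise FittingError("all ensemble members failed: " + "; ".join(errors[:3]))

    weights = ensemble_weights(
        np.array([m.fit_score for m in members]),
        np.array([m.total_variation for m in members]),
        lambda_tv,
    )
    for m in members:
        m.trimmed_ids = frozenset(trimmed)
    return SignalModel(members=members, weights=weights, trimmed_ids=frozenset(trimmed))
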