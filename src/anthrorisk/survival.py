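"""Cox proportional-hazard fitting on the age timescale.

Age is the analysis timescale, so every subject enters the risk set at the
age of examination (delayed entry / left truncation) and leaves at the age of
death or censoring.  The module provides:

* a weighted Cox partial likelihood with Efron tie handling
  (:func:`partial_log_likelihood` and the internal Newton engine),
* linear fits (:func:`fit_cox_linear`) and penalized-spline fits
  (:func:`fit_cox_spline`) of an index z-score, adjusted for sex and race,
* AICc-based smoothing selection, AIC difference tables, explained variation
  and a delayed-entry Harrell concordance.

Implementation notes
--------------------
Risk-set sums at each event age ``t`` are differences of two suffix sums
(over subjects with ``exit >= t`` minus subjects with ``entry >= t``), which
makes one likelihood/gradient evaluation O(n log n + n p).  The observed
information is accumulated without materializing per-event outer-product
sums: the risk-set second-moment term collapses to a single weighted Gram
matrix once per-event coefficients are swept back onto subjects via prefix
sums over event ages.  Sample weights enter as case weights; variance is
model-based.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .errors import (
    ComparabilityError,
    ConvergenceError,
    DomainError,
    InsufficientDataError,
    UndefinedConcordanceError,
    UndefinedLikelihoodError,
)

__all__ = [
    "SplineSpec",
    "CoxFit",
    "RiskCurve",
    "partial_log_likelihood",
    "fit_cox_linear",
    "fit_cox_baseline",
    "fit_cox_spline",
    "aicc",
    "delta_aic_table",
    "concordance_index",
    "explained_variation",
    "survival_frame",
]

logger = logging.getLogger(__name__)

#: AIC difference above which a model is significantly worse than the best.
DELTA_AIC_SIGNIFICANT = 6.0


def survival_frame(cohort: pd.DataFrame, keep: tuple[str, ...] = ()) -> pd.DataFrame:
    """Build an (entry_age, exit_age, event) frame from a cohort table.

    Entry is the age at examination; exit is entry plus follow-up.  Zero-length
    follow-up would put a subject at risk for an empty interval, so a tiny
    positive duration is required of the input.
    """
    out = pd.DataFrame(
        {
            "entry_age": cohort["age_years"].to_numpy(dtype=float),
            "exit_age": (
                cohort["age_years"].to_numpy(dtype=float)
                + cohort["followup_years"].to_numpy(dtype=float)
            ),
            "event": cohort["died"].to_numpy(dtype=int),
            "female": cohort["female"].to_numpy(dtype=float),
            "race_black": cohort["race_black"].to_numpy(dtype=float),
            "sample_weight": (
                cohort["sample_weight"].to_numpy(dtype=float)
                if "sample_weight" in cohort.columns
                else np.ones(len(cohort))
            ),
        }
    )
    for col in keep:
        out[col] = cohort[col].to_numpy(dtype=float)
    return out


class _CoxEngine:
    """Preprocessed risk-set structure for one (entry, exit, event, weight) sample."""

    def __init__(self, entry, exit_, event, weights=None):
        self.entry = np.asarray(entry, dtype=float)
        self.exit = np.asarray(exit_, dtype=float)
        self.event = np.asarray(event, dtype=bool)
        self.n = len(self.exit)
        self.w = (
            np.ones(self.n) if weights is None else np.asarray(weights, dtype=float)
        )
        if np.any(self.exit <= self.entry):
            raise DomainError("exit_age must be strictly greater than entry_age")
        if np.any(self.w < 0) or not np.all(np.isfinite(self.w)):
            raise DomainError("weights must be nonnegative and finite")
        if not self.event.any():
            raise UndefinedLikelihoodError("no events: partial likelihood undefined")

        self.n_events = int(self.event.sum())
        death_rows = np.flatnonzero(self.event)
        death_times = self.exit[death_rows]
        order = np.argsort(death_times, kind="stable")
        self.death_rows = death_rows[order]
        death_times = death_times[order]
        self.t_uniq, first_idx, self.d_per_time = np.unique(
            death_times, return_index=True, return_counts=True
        )
        K = len(self.t_uniq)
        self.death_group = np.repeat(np.arange(K), self.d_per_time)
        # Efron within-group fractions l/d, flattened over (time, l)
        self.rep = self.death_group
        self.phi = np.concatenate([np.arange(d) / d for d in self.d_per_time])
        wsum_d = np.bincount(self.death_group, weights=self.w[self.death_rows], minlength=K)
        self.wbar = wsum_d / self.d_per_time

        self.ord_exit = np.argsort(self.exit, kind="stable")
        self.ord_entry = np.argsort(self.entry, kind="stable")
        exit_sorted = self.exit[self.ord_exit]
        entry_sorted = self.entry[self.ord_entry]
        # subjects with exit >= t_k / entry >= t_k start at these positions
        self.bounds_exit = np.searchsorted(exit_sorted, self.t_uniq, side="left")
        self.bounds_entry = np.searchsorted(entry_sorted, self.t_uniq, side="left")
        # per-subject positions into prefix sums over event times (risk membership:
        # subject i is at risk at t_k iff entry_i < t_k <= exit_i)
        self.pos_exit = np.searchsorted(self.t_uniq, self.exit, side="right")
        self.pos_entry = np.searchsorted(self.t_uniq, self.entry, side="right")

    @staticmethod
    def _suffix(arr_sorted: np.ndarray) -> np.ndarray:
        """suffix[j] = sum(arr_sorted[j:]); one extra zero row so index n is valid."""
        c = np.cumsum(arr_sorted[::-1], axis=0)[::-1]
        pad = np.zeros((1,) + arr_sorted.shape[1:])
        return np.concatenate([c, pad], axis=0)

    def _risk_sums(self, values: np.ndarray):
        """Risk-set sums of per-subject values at each unique event time."""
        s_exit = self._suffix(values[self.ord_exit])[self.bounds_exit]
        s_entry = self._suffix(values[self.ord_entry])[self.bounds_entry]
        return s_exit - s_entry

    def loglik(self, eta, X=None, need_grad=False, need_hess=False):
        """Weighted Efron partial log-likelihood; optionally gradient/information.

        Returns (ll,), (ll, grad) or (ll, grad, info) where ``info`` is the
        negative Hessian (observed information) with respect to the
        coefficients of ``X`` (required for grad/hess).
        """
        eta = np.asarray(eta, dtype=float)
        eta = eta - eta.max()  # translation invariance; guards exp overflow
        v = self.w * np.exp(eta)
        di = self.death_rows
        g = self.death_group

        S0R = self._risk_sums(v)
        S0D = np.bincount(g, weights=v[di], minlength=len(self.t_uniq))
        S0 = S0R[self.rep] - self.phi * S0D[self.rep]
        if np.any(S0 <= 0):
            raise FloatingPointError("nonpositive risk-set sum (numerical degeneracy)")
        ll = float(np.sum(self.w[di] * eta[di]) - np.sum(self.wbar[self.rep] * np.log(S0)))
        if not (need_grad or need_hess):
            return (ll,)

        assert X is not None
        vX = v[:, None] * X
        S1R = self._risk_sums(vX)
        K, p = len(self.t_uniq), X.shape[1]
        S1D = np.zeros((K, p))
        np.add.at(S1D, g, vX[di])
        U = (S1R[self.rep] - self.phi[:, None] * S1D[self.rep]) / S0[:, None]
        grad = (self.w[di] @ X[di]) - (self.wbar[self.rep] @ U)
        if not need_hess:
            return ll, grad

        inv_S0 = 1.0 / S0
        a_k = np.bincount(self.rep, weights=self.wbar[self.rep] * inv_S0, minlength=K)
        b_k = np.bincount(self.rep, weights=self.wbar[self.rep] * self.phi * inv_S0, minlength=K)
        prefA = np.concatenate([[0.0], np.cumsum(a_k)])
        gA = prefA[self.pos_exit] - prefA[self.pos_entry]
        info = (X * (v * gA)[:, None]).T @ X
        info -= (X[di] * (v[di] * b_k[g])[:, None]).T @ X[di]
        info -= (U * self.wbar[self.rep][:, None]).T @ U
        return ll, grad, info


def partial_log_likelihood(entry, exit_, event, linear_predictor, weights=None) -> float:
    """Weighted Cox partial log-likelihood with delayed entry and Efron ties.

    The risk set at each event age t contains the subjects with
    ``entry < t <= exit``; tied event ages use the Efron correction with case
    weights.  Invariant to adding a constant to all linear predictors.
    """
    engine = _CoxEngine(entry, exit_, event, weights)
    return engine.loglik(np.asarray(linear_predictor, dtype=float))[0]


@dataclass
class CoxFit:
    """A fitted Cox model (linear or penalized-spline covariate effect)."""

    names: tuple
    coefficients: np.ndarray
    covariance: np.ndarray
    log_partial_likelihood: float
    null_log_partial_likelihood: float
    df_eff: float
    aic: float
    aicc: float
    n_events: int
    n: int
    label: str = ""
    form: str = "linear"
    hr_per_sd: float | None = None
    hr_ci: tuple | None = None
    concordance: float | None = None
    r_squared: float | None = None
    lambda_: float | None = None
    converged: bool = True
    separation_flag: bool = False


def _aicc_value(ll: float, df_eff: float, n_events: int) -> float:
    if n_events <= df_eff + 1:
        warnings.warn(
            "AICc correction undefined (n_events <= df_eff + 1); returning +inf",
            stacklevel=2,
        )
        return float("inf")
    return -2.0 * ll + 2.0 * df_eff + 2.0 * df_eff * (df_eff + 1.0) / (n_events - df_eff - 1.0)


def aicc(fit: CoxFit) -> float:
    """Corrected AIC of a fit, using effective df and the event count."""
    return _aicc_value(fit.log_partial_likelihood, fit.df_eff, fit.n_events)


def _newton(engine: _CoxEngine, X, penalty=None, lam=0.0, beta0=None, max_iter=60, tol=1e-9):
    """Maximize ll(beta) - lam/2 * beta' P beta by damped Newton iteration."""
    p = X.shape[1]
    P = np.zeros((p, p)) if penalty is None else penalty
    beta = np.zeros(p) if beta0 is None else beta0.copy()

    def objective(b):
        (ll,) = engine.loglik(X @ b)
        return ll - 0.5 * lam * b @ P @ b, ll

    obj, ll = objective(beta)
    info = None
    for it in range(max_iter):
        ll, grad, info = engine.loglik(X @ beta, X, need_grad=True, need_hess=True)
        pen_grad = grad - lam * P @ beta
        pen_info = info + lam * P
        try:
            step = cho_solve(cho_factor(pen_info), pen_grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(pen_info + 1e-8 * np.eye(p), pen_grad, rcond=None)[0]
        # damped step: halve until the penalized objective does not decrease
        scale, accepted = 1.0, False
        for _ in range(40):
            cand = beta + scale * step
            try:
                obj_new, ll_new = objective(cand)
            except FloatingPointError:
                obj_new = -np.inf
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            break
        improved = obj_new - obj
        beta, obj, ll = cand, obj_new, ll_new
        if improved < tol * (1.0 + abs(obj)) and np.max(np.abs(scale * step)) < 1e-6:
            return beta, ll, info, True, it + 1
    # final information at the returned point
    ll, _, info = engine.loglik(X @ beta, X, need_grad=True, need_hess=True)
    grad_norm = np.max(np.abs(engine.loglik(X @ beta, X, need_grad=True)[1] - lam * P @ beta))
    return beta, ll, info, grad_norm < 1e-4, max_iter


def _null_loglik(engine: _CoxEngine) -> float:
    return engine.loglik(np.zeros(engine.n))[0]


def _metrics(engine: _CoxEngine, eta, ll, ll_null):
    c = concordance_index(engine.entry, engine.exit, engine.event, eta, engine.w)
    r2 = _explained_variation_value(ll, ll_null, engine.n_events)
    return c, r2


def _explained_variation_value(ll_model: float, ll_null: float, m: int) -> float:
    if ll_model < ll_null:
        warnings.warn("model log-likelihood below null; clamping R^2 to 0", stacklevel=2)
        return 0.0
    return 1.0 - float(np.exp(2.0 * (ll_null - ll_model) / m))


def explained_variation(fit: CoxFit, null_fit: CoxFit | None = None) -> float:
    """Proportion of variation in mortality explained vs. a null model.

    Uses the likelihood-ratio based measure
    ``R^2 = 1 - exp(2*(l_null - l_model)/m)`` with ``m`` the number of events
    (a documented stand-in convention; negative values clamp to 0).  By
    default the null is the no-predictor model stored on the fit.
    """
    if null_fit is not None:
        if null_fit.n_events != fit.n_events:
            raise ComparabilityError("fits computed on different cohorts (event counts differ)")
        ll_null = null_fit.log_partial_likelihood
    else:
        ll_null = fit.null_log_partial_likelihood
    return _explained_variation_value(fit.log_partial_likelihood, ll_null, fit.n_events)


def _linear_fit(
    frame: pd.DataFrame,
    covariates: tuple[str, ...],
    use_sample_weights: bool,
    compute_metrics: bool,
    label: str,
    form: str = "linear",
    hr_index: int | None = 0,
) -> CoxFit:
    w = frame["sample_weight"].to_numpy(dtype=float) if use_sample_weights else None
    engine = _CoxEngine(
        frame["entry_age"], frame["exit_age"], frame["event"], weights=w
    )
    X = frame[list(covariates)].to_numpy(dtype=float)
    if X.shape[1] and np.any(np.ptp(X, axis=0) == 0):
        const = [c for c, r in zip(covariates, np.ptp(X, axis=0)) if r == 0]
        raise DomainError(f"constant covariate(s) {const}: zero variance")
    beta, ll, info, converged, n_iter = _newton(engine, X)
    if not converged:
        raise ConvergenceError(
            f"Cox linear fit {label!r} did not converge after {n_iter} iterations"
        )
    separation = bool(np.any(np.abs(beta) > 30))
    if separation:
        logger.warning("possible separation in fit %r: |beta| > 30", label)
    cov = np.linalg.inv(info)
    ll_null = _null_loglik(engine)
    k = X.shape[1]
    fit = CoxFit(
        names=tuple(covariates),
        coefficients=beta,
        covariance=cov,
        log_partial_likelihood=ll,
        null_log_partial_likelihood=ll_null,
        df_eff=float(k),
        aic=-2.0 * ll + 2.0 * k,
        aicc=_aicc_value(ll, float(k), engine.n_events),
        n_events=engine.n_events,
        n=engine.n,
        label=label,
        form=form,
        converged=converged,
        separation_flag=separation,
    )
    if hr_index is not None:
        se = float(np.sqrt(cov[hr_index, hr_index]))
        b = float(beta[hr_index])
        fit.hr_per_sd = float(np.exp(b))
        fit.hr_ci = (float(np.exp(b - 1.959964 * se)), float(np.exp(b + 1.959964 * se)))
    if compute_metrics:
        fit.concordance, fit.r_squared = _metrics(engine, X @ beta, ll, ll_null)
    return fit


def fit_cox_linear(
    frame: pd.DataFrame,
    covariate: str,
    adjusters: tuple[str, ...] = ("female", "race_black"),
    use_sample_weights: bool = True,
    compute_metrics: bool = True,
    label: str | None = None,
) -> CoxFit:
    """Linear proportional-hazard fit of one index z-score plus adjusters.

    ``frame`` needs columns entry_age, exit_age, event, sample_weight, the
    covariate and the adjusters.  Reports the hazard ratio per SD increase of
    the covariate with a Wald 95% CI.
    """
    return _linear_fit(
        frame,
        (covariate, *adjusters),
        use_sample_weights,
        compute_metrics,
        label or covariate,
    )


def fit_cox_baseline(
    frame: pd.DataFrame,
    adjusters: tuple[str, ...] = ("female", "race_black"),
    use_sample_weights: bool = True,
    compute_metrics: bool = True,
) -> CoxFit:
    """Adjusters-only baseline model (the "no anthropometry" comparison row)."""
    return _linear_fit(
        frame, tuple(adjusters), use_sample_weights, compute_metrics, "None",
        form="baseline", hr_index=None,
    )


# ---------------------------------------------------------------------------
# Penalized splines
# ---------------------------------------------------------------------------


@dataclass
class SplineSpec:
    """Penalized-spline configuration for the nonlinear covariate effect.

    Cubic B-splines with interior knots at covariate quantiles and a penalty
    on the integrated squared ``penalty_order``-th derivative.  That penalty's
    null space is exactly the polynomials of degree < penalty_order for any
    knot placement, so at the heavy-smoothing end of ``lambda_grid`` the fit
    collapses onto the linear model.
    """

    basis_degree: int = 3
    n_interior_knots: int = 10
    knot_placement: str = "quantile"
    penalty_order: int = 2
    lambda_grid: np.ndarray = field(default_factory=lambda: np.logspace(-2.0, 6.0, 33))

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if self.basis_degree < 1 or self.n_interior_knots < 1:
            raise DomainError("basis_degree and n_interior_knots must be >= 1")
        if self.penalty_order < 1 or self.penalty_order > self.basis_degree:
            raise DomainError("penalty_order must be in [1, basis_degree]")
        if np.any(self.lambda_grid <= 0):
            raise DomainError("lambda_grid must be positive")

    @property
    def n_basis(self) -> int:
        return self.basis_degree + 1 + self.n_interior_knots


def _knot_vector(z: np.ndarray, spec: SplineSpec) -> np.ndarray:
    lo, hi = float(np.min(z)), float(np.max(z))
    if hi - lo < 1e-8:
        raise DomainError("covariate range too narrow for knot placement")
    if spec.knot_placement == "quantile":
        probs = np.arange(1, spec.n_interior_knots + 1) / (spec.n_interior_knots + 1)
        interior = np.quantile(z, probs)
    elif spec.knot_placement == "uniform":
        interior = np.linspace(lo, hi, spec.n_interior_knots + 2)[1:-1]
    else:
        raise DomainError(f"unknown knot_placement {spec.knot_placement!r}")
    interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
    if np.any(np.diff(interior) <= 1e-10 * (hi - lo)):
        raise DomainError(
            "covariate distribution too concentrated: coincident interior knots"
        )
    deg = spec.basis_degree
    return np.concatenate([[lo] * (deg + 1), interior, [hi] * (deg + 1)])


def _basis_matrix(knots: np.ndarray, degree: int, z: np.ndarray) -> np.ndarray:
    """Evaluate all basis functions at z (clipped to the knot span)."""
    m = len(knots) - degree - 1
    zc = np.clip(z, knots[0], knots[-1])
    B = np.empty((len(zc), m))
    for j in range(m):
        coef = np.zeros(m)
        coef[j] = 1.0
        B[:, j] = BSpline(knots, coef, degree, extrapolate=True)(zc)
    return B


def _derivative_penalty(knots: np.ndarray, degree: int, order: int) -> np.ndarray:
    """P[j,k] = integral of B_j^(order) * B_k^(order) over the knot span.

    Exact via Gauss-Legendre: the integrand is piecewise polynomial of degree
    2*(degree-order) on each inter-knot interval.
    """
    m = len(knots) - degree - 1
    breaks = np.unique(knots)
    npts = max(degree - order + 1, 1)
    xg, wg = np.polynomial.legendre.leggauss(npts)
    splines = []
    for j in range(m):
        coef = np.zeros(m)
        coef[j] = 1.0
        splines.append(BSpline(knots, coef, degree).derivative(order))
    P = np.zeros((m, m))
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        x = mid + half * xg
        D = np.column_stack([s(x) for s in splines])
        P += half * (D * wg[:, None]).T @ D
    return P


def _ones_complement(m: int) -> np.ndarray:
    """Orthonormal basis of the subspace orthogonal to the constant direction.

    Adding a constant to all B-spline coefficients shifts the linear predictor
    by a constant, which the partial likelihood cannot identify; fitting is
    done in this reduced parametrization.
    """
    # Helmert contrasts, orthonormalized: deterministic across platforms
    T = np.zeros((m, m - 1))
    for j in range(1, m):
        T[:j, j - 1] = 1.0
        T[j, j - 1] = -j
        T[:, j - 1] /= np.sqrt(j * (j + 1))
    return T


@dataclass
class RiskCurve:
    """A centered log-hazard-ratio function of an index z-score.

    The curve is stored as a B-spline (knots, degree, coefficients) with a
    centering offset chosen so the weighted mean of the curve over the fitting
    cohort is zero; outside ``valid_range`` evaluation clamps to the boundary
    values.  A redundant evaluation grid (z = -4..4, step 0.05) with pointwise
    SEs is kept for portability and plotting.
    """

    knots: np.ndarray
    degree: int
    coefficients: np.ndarray
    centering_offset: float
    valid_range: tuple[float, float]
    z_grid: np.ndarray
    log_hr: np.ndarray
    pointwise_se: np.ndarray
    coef_cov: np.ndarray | None = None
    index_name: str = ""

    def evaluate(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        lo, hi = self.valid_range
        n_out = int(np.sum((z < lo) | (z > hi)))
        if n_out:
            logger.info(
                "risk curve %s: clamping %d value(s) outside [%g, %g]",
                self.index_name or "<unnamed>", n_out, lo, hi,
            )
        zc = np.clip(z, lo, hi)
        val = BSpline(self.knots, self.coefficients, self.degree, extrapolate=True)(zc)
        return val - self.centering_offset

    def evaluate_se(self, z) -> np.ndarray:
        if self.coef_cov is None:
            raise DomainError("risk curve carries no coefficient covariance")
        zc = np.clip(np.asarray(z, dtype=float), *self.valid_range)
        B = _basis_matrix(self.knots, self.degree, zc)
        return np.sqrt(np.einsum("ij,jk,ik->i", B, self.coef_cov, B))

    def to_json_dict(self) -> dict:
        d = {
            "knots": self.knots.tolist(),
            "degree": int(self.degree),
            "coefficients": self.coefficients.tolist(),
            "centering_offset": float(self.centering_offset),
            "valid_range": [float(self.valid_range[0]), float(self.valid_range[1])],
            "z_grid": self.z_grid.tolist(),
            "log_hr": self.log_hr.tolist(),
            "pointwise_se": self.pointwise_se.tolist(),
            "index_name": self.index_name,
        }
        if self.coef_cov is not None:
            d["coef_cov"] = self.coef_cov.tolist()
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "RiskCurve":
        return cls(
            knots=np.asarray(d["knots"], dtype=float),
            degree=int(d["degree"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            centering_offset=float(d["centering_offset"]),
            valid_range=(float(d["valid_range"][0]), float(d["valid_range"][1])),
            z_grid=np.asarray(d["z_grid"], dtype=float),
            log_hr=np.asarray(d["log_hr"], dtype=float),
            pointwise_se=np.asarray(d["pointwise_se"], dtype=float),
            coef_cov=(
                np.asarray(d["coef_cov"], dtype=float) if "coef_cov" in d else None
            ),
            index_name=d.get("index_name", ""),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True)

    def grid_frame(self) -> pd.DataFrame:
        """Figure-style export: z, log HR, SE, HR and 95% CI bounds."""
        hr = np.exp(self.log_hr)
        return pd.DataFrame(
            {
                "z": self.z_grid,
                "log_hr": self.log_hr,
                "se": self.pointwise_se,
                "hr": hr,
                "hr_lo95": np.exp(self.log_hr - 1.959964 * self.pointwise_se),
                "hr_hi95": np.exp(self.log_hr + 1.959964 * self.pointwise_se),
            }
        )


def fit_cox_spline(
    frame: pd.DataFrame,
    covariate: str,
    spec: SplineSpec | None = None,
    adjusters: tuple[str, ...] = ("female", "race_black"),
    use_sample_weights: bool = True,
    compute_metrics: bool = True,
    label: str | None = None,
) -> tuple[CoxFit, RiskCurve]:
    """Penalized-spline Cox fit with AICc-selected smoothing.

    For each lambda on the grid (swept from smoothest to roughest with warm
    starts) the penalized partial likelihood ``l(beta) - lambda/2 b'Pb`` is
    maximized (penalty on the spline coefficients only); the effective df is
    ``trace[(H + lambda P)^{-1} H]`` with H the observed information at the
    optimum, and the lambda minimizing AICc is selected.  Returns the selected
    fit and its centered :class:`RiskCurve` with pointwise SEs from the
    penalized covariance.
    """
    spec = spec or SplineSpec()
    label = label or covariate
    w = frame["sample_weight"].to_numpy(dtype=float) if use_sample_weights else None
    engine = _CoxEngine(frame["entry_age"], frame["exit_age"], frame["event"], weights=w)
    if engine.n_events < 20:
        logger.warning(
            "spline fit %r: only %d events (>= 20 recommended)", label, engine.n_events
        )
    z = frame[covariate].to_numpy(dtype=float)
    knots = _knot_vector(z, spec)
    B = _basis_matrix(knots, spec.basis_degree, z)
    m = B.shape[1]
    T = _ones_complement(m)
    Bc = B @ T
    A = frame[list(adjusters)].to_numpy(dtype=float) if adjusters else np.empty((len(z), 0))
    X = np.column_stack([Bc, A])
    p = X.shape[1]
    P_spline = T.T @ _derivative_penalty(knots, spec.basis_degree, spec.penalty_order) @ T
    P = np.zeros((p, p))
    P[: m - 1, : m - 1] = P_spline

    lam_desc = np.sort(spec.lambda_grid)[::-1]
    beta = None
    best = None
    any_converged = False
    for lam in lam_desc:
        beta, ll, info, converged, _ = _newton(engine, X, P, lam, beta0=beta)
        if not converged:
            continue
        any_converged = True
        pen_info = info + lam * P
        try:
            cf = cho_factor(pen_info)
            df_eff = float(np.trace(cho_solve(cf, info)))
            cov_pen = cho_solve(cf, np.eye(p))
        except np.linalg.LinAlgError:
            continue
        crit = _aicc_value(ll, df_eff, engine.n_events)
        if best is None or crit < best["aicc"]:
            best = dict(
                lam=float(lam), beta=beta.copy(), ll=ll, info=info,
                df_eff=df_eff, cov=cov_pen, aicc=crit,
            )
    if not any_converged or best is None:
        raise ConvergenceError(f"spline fit {label!r}: no lambda on the grid converged")

    beta, ll, lam = best["beta"], best["ll"], best["lam"]
    cov = best["cov"]
    df_eff = best["df_eff"]
    ll_null = _null_loglik(engine)
    fit = CoxFit(
        names=tuple(f"spline_{j}" for j in range(m - 1)) + tuple(adjusters),
        coefficients=beta,
        covariance=cov,
        log_partial_likelihood=ll,
        null_log_partial_likelihood=ll_null,
        df_eff=df_eff,
        aic=-2.0 * ll + 2.0 * df_eff,
        aicc=best["aicc"],
        n_events=engine.n_events,
        n=engine.n,
        label=label,
        form="nonlinear",
        lambda_=lam,
        converged=True,
    )
    if compute_metrics:
        fit.concordance, fit.r_squared = _metrics(engine, X @ beta, ll, ll_null)

    coef_full = T @ beta[: m - 1]
    cov_full = T @ cov[: m - 1, : m - 1] @ T.T
    weights_fit = engine.w / engine.w.sum()
    offset = float(weights_fit @ (B @ coef_full))
    z_grid = np.round(np.arange(-4.0, 4.0 + 1e-9, 0.05), 10)
    lo, hi = float(np.min(z)), float(np.max(z))
    zc = np.clip(z_grid, lo, hi)
    Bg = _basis_matrix(knots, spec.basis_degree, zc)
    curve = RiskCurve(
        knots=knots,
        degree=spec.basis_degree,
        coefficients=coef_full,
        centering_offset=offset,
        valid_range=(lo, hi),
        z_grid=z_grid,
        log_hr=Bg @ coef_full - offset,
        pointwise_se=np.sqrt(np.einsum("ij,jk,ik->i", Bg, cov_full, Bg)),
        coef_cov=cov_full,
        index_name=label,
    )
    return fit, curve


# ---------------------------------------------------------------------------
# Model comparison metrics
# ---------------------------------------------------------------------------


def delta_aic_table(fits: dict[str, CoxFit]) -> pd.DataFrame:
    """AIC difference table, sorted by increasing delta (decreasing skill).

    ``delta_i = AIC_i - min AIC``; models with delta > 6 are flagged as
    performing significantly worse than the best model.
    """
    if not fits:
        raise InsufficientDataError("no fits to compare")
    n_events = {f.n_events for f in fits.values()}
    if len(n_events) > 1:
        raise ComparabilityError(
            f"fits have mismatched event counts {sorted(n_events)}: not comparable"
        )
    rows = [(name, f.aic) for name, f in fits.items()]
    best = min(a for _, a in rows)
    table = pd.DataFrame(
        [(name, a, a - best, a - best > DELTA_AIC_SIGNIFICANT) for name, a in rows],
        columns=["predictor", "aic", "delta_i", "significantly_worse"],
    )
    return table.sort_values("delta_i", kind="stable").reset_index(drop=True)


def concordance_index(entry, exit_, event, linear_predictor, weights=None) -> float:
    """Harrell-type concordance with delayed entry.

    A pair is comparable when one subject dies at age t while the other is
    under observation strictly beyond t (``entry < t < exit``); it is
    concordant when the subject who died sooner has the higher predictor.
    Predictor ties count 1/2; pairs are weighted by the product of sample
    weights.  Two deaths at the same age are not comparable.
    """
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    event = np.asarray(event, dtype=bool)
    lp = np.asarray(linear_predictor, dtype=float)
    w = np.ones(len(lp)) if weights is None else np.asarray(weights, dtype=float)
    num = 0.0
    den = 0.0
    for i in np.flatnonzero(event):
        t = exit_[i]
        at_risk = (entry < t) & (exit_ > t)
        if not at_risk.any():
            continue
        wj = w[at_risk]
        lpj = lp[at_risk]
        pair_w = w[i] * wj
        num += pair_w @ ((lp[i] > lpj) + 0.5 * (lp[i] == lpj))
        den += pair_w.sum()
    if den == 0:
        raise UndefinedConcordanceError("no comparable pairs under delayed entry")
    return float(num / den)
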