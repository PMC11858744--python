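"""Log-domain erf psychometric model parameterized by the Weber fraction.

The probability of judging a test of viscosity eta thicker than a reference p
is

    f(eta) = 0.5 + 0.5 * erf( log(eta / p) / (sqrt(2) * log(w + 1)) )

so f is a cumulative Gaussian in log viscosity whose slope is set directly by
the Weber fraction w: at eta = p*(1+w) the curve passes through
0.5 + 0.5*erf(1/sqrt(2)) ~ 0.8413, the conventional discriminability
threshold, and at eta = p/(1+w) through ~0.1587.  The log base cancels
between numerator and denominator; natural log is used throughout.

Fitting maximizes the independent-binomial likelihood of the pooled k/n
counts per test viscosity, over (log w, log p) within box constraints, in two
modes: ``fixed_p`` pins p at the true reference (symmetric discrimination
tasks, w is the Weber fraction), ``free_p`` fits p as the point of subjective
equality (bias tasks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize
from scipy.special import erf

from .data import ResponseTable, ValidationError

logger = logging.getLogger(__name__)

#: probability clip guarding log(0) at extreme parameters
PROB_EPS = 1e-9

#: default box constraints and initial Weber fraction used by fits
DEFAULT_W_BOUNDS = (0.1, 100.0)
DEFAULT_P_BOUNDS = (10.0, 20500.0)
DEFAULT_W_INIT = 0.5

#: relative distance to a bound below which a fit is declared bound-pinned
_BOUND_RTOL = 1e-4


@dataclass(frozen=True)
class PsychometricParams:
    """Model parameters: Weber fraction ``w`` and reference/PSE ``p`` (cP)."""

    w: float
    p: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and np.isfinite(self.w)):
            raise ValidationError(f"w must be positive and finite, got {self.w}")
        if not (self.p > 0 and np.isfinite(self.p)):
            raise ValidationError(f"p must be positive and finite, got {self.p}")


@dataclass(frozen=True)
class FitConstraints:
    """Box bounds and initial values for maximum-likelihood fitting."""

    w_bounds: tuple[float, float] = DEFAULT_W_BOUNDS
    p_bounds: tuple[float, float] = DEFAULT_P_BOUNDS
    w_init: float = DEFAULT_W_INIT
    p_init: float | None = None  # default: the true reference viscosity

    def __post_init__(self) -> None:
        if not self.w_bounds[0] < self.w_bounds[1]:
            raise ValidationError("w_bounds must be an increasing interval")
        if not self.p_bounds[0] < self.p_bounds[1]:
            raise ValidationError("p_bounds must be an increasing interval")
        if not self.w_bounds[0] <= self.w_init <= self.w_bounds[1]:
            raise ValidationError("w_init outside w_bounds")
        if self.p_init is not None and not (
            self.p_bounds[0] <= self.p_init <= self.p_bounds[1]
        ):
            raise ValidationError("p_init outside p_bounds")


@dataclass(frozen=True)
class PsychometricFit:
    """A fitted model plus fit metadata.

    ``converged`` is False for degenerate data or an optimum pinned at a box
    bound; ``optimizer_success`` records only whether the numerical optimizer
    itself terminated normally (a bound-pinned fit still counts as a
    successful optimization).
    """

    params: PsychometricParams
    mode: str  # "fixed_p" | "free_p"
    log_likelihood: float
    converged: bool
    n_points: int
    p_fixed_value: float | None = None
    optimizer_success: bool = True


class Jnd(NamedTuple):
    lower: float
    upper: float


def _curve(eta: np.ndarray | float, w: float, p: float) -> np.ndarray | float:
    return 0.5 + 0.5 * erf(np.log(np.asarray(eta, dtype=float) / p)
                           / (np.sqrt(2.0) * np.log(w + 1.0)))


def predict(eta: float | np.ndarray, params: PsychometricParams) -> float | np.ndarray:
    """Probability of a 'test thicker' response at test viscosity ``eta``."""
    eta_arr = np.asarray(eta, dtype=float)
    if np.any(eta_arr <= 0) or not np.all(np.isfinite(eta_arr)):
        raise ValidationError("eta must be positive and finite")
    out = _curve(eta_arr, params.w, params.p)
    return float(out) if np.isscalar(eta) or eta_arr.ndim == 0 else out


def negative_log_likelihood(table: ResponseTable, params: PsychometricParams) -> float:
    """Binomial NLL of the aggregated counts under the model (up to the
    constant log binomial coefficients, which do not depend on parameters)."""
    if not table.rows:
        raise ValidationError("empty response table")
    eta, k, n = table.arrays()
    f = np.clip(_curve(eta, params.w, params.p), PROB_EPS, 1.0 - PROB_EPS)
    return float(-np.sum(k * np.log(f) + (n - k) * np.log(1.0 - f)))


def _nll_arrays(eta: np.ndarray, k: np.ndarray, n: np.ndarray,
                w: float, p: float) -> float:
    f = np.clip(_curve(eta, w, p), PROB_EPS, 1.0 - PROB_EPS)
    return float(-np.sum(k * np.log(f) + (n - k) * np.log(1.0 - f)))


def _near(value: float, bound: float) -> bool:
    return abs(np.log(value) - np.log(bound)) <= _BOUND_RTOL


def fit(
    table: ResponseTable,
    mode: str = "fixed_p",
    constraints: FitConstraints | None = None,
    true_reference: float | None = None,
) -> PsychometricFit:
    """Constrained maximum-likelihood fit of the psychometric model.

    Optimization runs in (log w, log p) coordinates.  ``fixed_p`` requires
    ``true_reference`` and reduces to a bounded one-dimensional search for w.
    A fit whose optimum touches a box bound is reported at the bound with
    ``converged=False``; optimizer failures likewise never raise.
    """
    if mode not in ("fixed_p", "free_p"):
        raise ValidationError(f"unknown fit mode {mode!r}")
    if len(table.rows) < 2:
        raise ValidationError("need at least 2 response rows to fit")
    cons = constraints or FitConstraints()
    eta, k, n = table.arrays()
    w_lo, w_hi = cons.w_bounds
    degenerate = bool(np.all(k == 0) or np.all(k == n))

    if mode == "fixed_p":
        if true_reference is None:
            raise ValidationError("fixed_p mode requires true_reference")
        p_hat = float(true_reference)
        res = optimize.minimize_scalar(
            lambda lw: _nll_arrays(eta, k, n, float(np.exp(lw)), p_hat),
            bounds=(np.log(w_lo), np.log(w_hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        w_hat = float(np.exp(res.x))
        nll = float(res.fun)
        converged = bool(res.success) and not (
            _near(w_hat, w_lo) or _near(w_hat, w_hi)
        )
        if degenerate:
            converged = False
        params = PsychometricParams(w_hat, p_hat)
        if not converged:
            logger.debug(
                "fixed_p fit not converged (w=%.4g at bounds or degenerate data)", w_hat
            )
        return PsychometricFit(
            params, mode, -nll, converged, len(table.rows), p_hat,
            optimizer_success=bool(res.success),
        )

    # free_p
    p_lo, p_hi = cons.p_bounds
    p_init = cons.p_init if cons.p_init is not None else (
        float(true_reference) if true_reference is not None
        else float(np.clip(table.reference_viscosity, p_lo, p_hi))
    )
    x0 = np.array([np.log(cons.w_init), np.log(p_init)])
    bounds = [(np.log(w_lo), np.log(w_hi)), (np.log(p_lo), np.log(p_hi))]

    def objective(x: np.ndarray) -> float:
        return _nll_arrays(eta, k, n, float(np.exp(x[0])), float(np.exp(x[1])))

    # bounded simplex is the primary optimizer: the finite-difference gradient
    # of L-BFGS-B stalls on occasional resampled tables, simplex does not
    best = optimize.minimize(
        objective, x0, method="Nelder-Mead", bounds=bounds,
        options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 2000},
    )
    if not best.success:
        res_grad = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-9},
        )
        if res_grad.fun <= best.fun:
            best = res_grad
    w_hat = float(np.exp(best.x[0]))
    p_hat = float(np.exp(best.x[1]))
    converged = bool(best.success) and not any(
        _near(v, b) for v, bs in ((w_hat, cons.w_bounds), (p_hat, cons.p_bounds))
        for b in bs
    )
    if degenerate:
        converged = False
    params = PsychometricParams(w_hat, p_hat)
    return PsychometricFit(
        params, mode, -float(best.fun), converged, len(table.rows),
        optimizer_success=bool(best.success),
    )


def jnd(params: PsychometricParams) -> Jnd:
    """Just-noticeable-difference bounds: p/(1+w) and p*(1+w) (the 16%/84%
    response points of the fitted curve)."""
    return Jnd(lower=params.p / (1.0 + params.w), upper=params.p * (1.0 + params.w))
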