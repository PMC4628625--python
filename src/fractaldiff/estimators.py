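"""Scikit-learn style estimators for anomalous-diffusion parameters.

Three fitting strategies for MSD-versus-time data, all built on the
implicit crossover equation of :mod:`fractaldiff.model`:

``SinglePointMSDFit``
    Exact inversion from one (t, MSD) observation with the mean free path
    lambda and step time tau calibrated beforehand from ordinary
    diffusion; alpha is the root of model(t; alpha) = MSD.
``CalibratedMSDFit``
    Relative least squares over alpha alone, again with (lambda, tau)
    fixed; the transport coefficient is tied to alpha through
    Gamma = 2^(-alpha) lambda^2 / tau^alpha, which is what makes short
    time series informative.
``FreeMSDFit``
    Joint (alpha, Gamma) fit given only the unobstructed diffusion
    coefficient D, internally parameterized by (alpha, ln tau) with
    Gamma = D (2 tau)^(1-alpha) so the objective is smooth at alpha = 1.

All estimators follow the sklearn contract: hyperparameters in
``__init__``, data only in ``fit(X, y)`` (X = times, column vector or 1D;
y = MSD in the canonical 2D convention), fitted attributes with trailing
underscores, and ``predict(X)`` returning model MSD values, so they
compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    InfeasibleObservationError,
    InsufficientDataError,
    InvalidInputError,
    NoSolutionError,
)
from .model import msd_normalized, transport_coefficient
from .params import ALPHA_MIN, WalkParameters
from .series import FitResult

__all__ = ["SinglePointMSDFit", "CalibratedMSDFit", "FreeMSDFit"]


def _as_time_msd(X, y) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise InvalidInputError("X must be a 1D array of times or a column vector")
    m = np.asarray(y, dtype=float).ravel()
    if len(t) != len(m):
        raise InvalidInputError("times and MSD values must have equal length")
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing and > 0")
    if np.any(m <= 0):
        raise InvalidInputError("MSD values must be > 0")
    return t, m


class _BaseMSDFit(BaseEstimator, RegressorMixin):
    """Shared plumbing: prediction and FitResult export."""

    def _model_msd(self, t: np.ndarray, alpha: float) -> np.ndarray:
        y = msd_normalized(t / self.tau, alpha, self.k)
        return self.lambda_mfp**2 * np.asarray(y)

    def predict(self, X):
        """Model MSD (2D convention) at the given times."""
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        params = WalkParameters(self.lambda_used_, self.tau_used_,
                                self.alpha_, self.k)
        y = msd_normalized(t / params.tau, params.alpha, params.k)
        return params.lambda_mfp**2 * np.asarray(y)

    def result_(self) -> FitResult:
        """Export the fitted state as a :class:`FitResult`."""
        return FitResult(
            alpha_hat=self.alpha_,
            gamma_hat=self.gamma_,
            lambda_used=self.lambda_used_,
            tau_used=self.tau_used_,
            v0=self.lambda_used_ / self.tau_used_,
            residual_norm=self.residual_norm_,
            n_points=self.n_points_,
            method=self._method,
            at_boundary=self.at_boundary_,
            flat_objective=getattr(self, "flat_objective_", False),
        )


class SinglePointMSDFit(_BaseMSDFit):
    """Invert alpha (and hence Gamma) from a single short-time MSD point.

    Parameters
    ----------
    lambda_mfp, tau : float
        Mean free path and Brownian step time calibrated from ordinary
        diffusion of the same species.
    alpha_bounds : (float, float)
        Search interval for the exponent, default (0.05, 2).
    grid_size : int
        Nodes of the coarse sign-change scan that brackets the root.
    """

    _method = "single_point"

    def __init__(self, lambda_mfp: float = 1.0, tau: float = 1.0,
                 k: float = 2.0,
                 alpha_bounds: Tuple[float, float] = (ALPHA_MIN, 2.0),
                 grid_size: int = 40):
        self.lambda_mfp = lambda_mfp
        self.tau = tau
        self.k = k
        self.alpha_bounds = alpha_bounds
        self.grid_size = grid_size

    def fit(self, X, y):
        t, m = _as_time_msd(X, y)
        if len(t) != 1:
            raise InvalidInputError(
                "SinglePointMSDFit takes exactly one (t, MSD) observation")
        t0, m0 = float(t[0]), float(m[0])
        ballistic = (self.lambda_mfp * t0 / self.tau) ** 2
        if m0 >= ballistic:
            raise InfeasibleObservationError(
                f"MSD {m0:g} at t={t0:g} is at or above the ballistic bound "
                f"{ballistic:g}; no alpha <= 2 can produce it")

        def h(alpha: float) -> float:
            return float(self._model_msd(t[:1], alpha)[0]) - m0

        lo, hi = self.alpha_bounds
        grid = np.linspace(lo, hi, self.grid_size + 1)
        vals = np.array([h(a) for a in grid])
        sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if len(sign_change) == 0:
            if np.any(vals == 0.0):
                alpha_hat = float(grid[np.argmin(np.abs(vals))])
            else:
                raise NoSolutionError(
                    f"no alpha in [{lo}, {hi}] reproduces MSD {m0:g} at "
                    f"t={t0:g}", interval=(lo, hi))
        else:
            i = sign_change[0]
            alpha_hat = brentq(h, grid[i], grid[i + 1],
                               xtol=1e-12, rtol=8.9e-16)
        self.alpha_ = float(alpha_hat)
        self.lambda_used_ = self.lambda_mfp
        self.tau_used_ = self.tau
        self.gamma_ = transport_coefficient(
            WalkParameters(self.lambda_mfp, self.tau, self.alpha_, self.k))
        self.residual_norm_ = 0.0
        self.n_points_ = 1
        self.at_boundary_ = min(self.alpha_ - lo, hi - self.alpha_) < 1e-9
        return self


class CalibratedMSDFit(_BaseMSDFit):
    """Least-squares alpha fit with (lambda, tau) fixed and Gamma tied.

    Minimizes sum_i (model(t_i; alpha)/MSD_i - 1)^2, a relative criterion
    chosen because MSD magnitudes span decades; a coarse grid pre-scan
    (step ``grid_step``) guards against local minima before bounded local
    refinement to ``xatol``.
    """

    _method = "least_squares"

    def __init__(self, lambda_mfp: float = 1.0, tau: float = 1.0,
                 k: float = 2.0,
                 alpha_bounds: Tuple[float, float] = (ALPHA_MIN, 2.0),
                 grid_step: float = 0.05, xatol: float = 1e-8):
        self.lambda_mfp = lambda_mfp
        self.tau = tau
        self.k = k
        self.alpha_bounds = alpha_bounds
        self.grid_step = grid_step
        self.xatol = xatol

    def _objective(self, alpha: float, t: np.ndarray, m: np.ndarray) -> float:
        return float(np.sum((self._model_msd(t, alpha) / m - 1.0) ** 2))

    def fit(self, X, y):
        t, m = _as_time_msd(X, y)
        if len(t) < 2:
            raise InsufficientDataError(
                "least-squares fit needs >= 2 points; use SinglePointMSDFit")
        lo, hi = self.alpha_bounds
        n_grid = max(2, int(round((hi - lo) / self.grid_step)))
        grid = np.linspace(lo, hi, n_grid + 1)
        J = np.array([self._objective(a, t, m) for a in grid])
        i = int(np.argmin(J))
        a_lo = grid[max(i - 1, 0)]
        a_hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(self._objective, args=(t, m), bounds=(a_lo, a_hi),
                              method="bounded",
                              options={"xatol": self.xatol, "maxiter": 500})
        alpha_hat = float(res.x)
        # the bounded minimizer never lands exactly on a bound; polish ends
        for a_edge in (lo, hi):
            if self._objective(a_edge, t, m) < res.fun:
                alpha_hat = a_edge
        self.alpha_ = alpha_hat
        self.lambda_used_ = self.lambda_mfp
        self.tau_used_ = self.tau
        self.gamma_ = transport_coefficient(
            WalkParameters(self.lambda_mfp, self.tau, self.alpha_, self.k))
        self.residual_norm_ = math.sqrt(self._objective(self.alpha_, t, m))
        self.n_points_ = len(t)
        self.at_boundary_ = min(self.alpha_ - lo, hi - self.alpha_) < 2 * self.xatol
        return self


class FreeMSDFit(_BaseMSDFit):
    """Joint (alpha, Gamma) fit given only the free diffusion coefficient D.

    Internally searches (alpha, ln tau): for each candidate pair the
    closure Gamma = D (2 tau)^(1-alpha) and lambda = sqrt(2 D tau) fix the
    full crossover curve, which is compared with the data by relative
    least squares.  This parameterization is smooth at alpha = 1 (where
    Gamma = D and tau is identified by the crossover position alone).
    The implied tau is reported for cross-validation against an
    independently calibrated step time.
    """

    _method = "free_fit"

    def __init__(self, D: float = 1.0, k: float = 2.0,
                 alpha_bounds: Tuple[float, float] = (ALPHA_MIN, 2.0),
                 n_grid_alpha: int = 25, n_grid_tau: int = 25,
                 xatol: float = 1e-10, flat_tol: float = 1e-12):
        self.D = D
        self.k = k
        self.alpha_bounds = alpha_bounds
        self.n_grid_alpha = n_grid_alpha
        self.n_grid_tau = n_grid_tau
        self.xatol = xatol
        self.flat_tol = flat_tol

    def _objective(self, alpha: float, log_tau: float,
                   t: np.ndarray, m: np.ndarray) -> float:
        tau = math.exp(log_tau)
        lam2 = 2.0 * self.D * tau
        y = np.asarray(msd_normalized(t / tau, alpha, self.k))
        return float(np.sum((lam2 * y / m - 1.0) ** 2))

    def fit(self, X, y):
        t, m = _as_time_msd(X, y)
        if len(t) < 3:
            raise InsufficientDataError("free fit needs >= 3 points")
        lo, hi = self.alpha_bounds
        alphas = np.linspace(lo, hi, self.n_grid_alpha)
        log_taus = np.log(np.geomspace(t[0] * 1e-5, t[-1] * 10.0,
                                       self.n_grid_tau))
        J = np.array([[self._objective(a, lt, t, m) for lt in log_taus]
                      for a in alphas])
        ia, it = np.unravel_index(np.argmin(J), J.shape)

        def obj(p):
            a = min(max(p[0], lo), hi)
            return self._objective(a, p[1], t, m)

        res = minimize(obj, x0=[alphas[ia], log_taus[it]],
                       method="Nelder-Mead",
                       options={"xatol": self.xatol, "fatol": 1e-24,
                                "maxiter": 4000, "maxfev": 4000})
        alpha_hat = float(min(max(res.x[0], lo), hi))
        tau_hat = float(math.exp(res.x[1]))
        self.alpha_ = alpha_hat
        self.tau_used_ = tau_hat
        self.tau_implied_ = tau_hat
        self.lambda_used_ = math.sqrt(2.0 * self.D * tau_hat)
        self.gamma_ = self.D * (2.0 * tau_hat) ** (1.0 - alpha_hat)
        self.residual_norm_ = math.sqrt(max(res.fun, 0.0))
        self.n_points_ = len(t)
        self.at_boundary_ = min(alpha_hat - lo, hi - alpha_hat) < 1e-9
        # flat objective: perturbing alpha noticeably must change the fit
        da = 0.05
        probe = [self._objective(a, res.x[1], t, m)
                 for a in (max(lo, alpha_hat - da), min(hi, alpha_hat + da))]
        self.flat_objective_ = all(
            abs(p - res.fun) <= self.flat_tol * (1.0 + res.fun) for p in probe)
        return self
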