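"""Closed-form fractal model of the ballistic-to-anomalous MSD crossover.

The model describes a walk made of straight segments of length lambda
traversed in time tau.  Coarse-graining the trajectory gives a
scale-dependent fractal dimension

    D_w(s) = D_w - (D_w - 1) / (1 + s/(k*Lambda)),

which interpolates from 1 (ballistic, scales below the mean free path) to
the asymptotic D_w = 2/alpha.  Integrating the fractal length relation
d ln L / d ln s = 1 - D_w(s) yields an implicit equation for the 2D mean
square displacement <r^2> at any time t,

    (x) * (k + x)^(D_w - 1) = k^(D_w - 1) * t/tau,   x = sqrt(<r^2>)/lambda,

whose two asymptotes are the ballistic law <r^2> = (v0 t)^2 and the
anomalous power law <r^2> = 4 Gamma t^alpha with
Gamma = 2^(-alpha) lambda^2 / tau^alpha (for the universal choice k = 2).

All functions are unit-agnostic; times and lengths must be self-consistent.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Union

import numpy as np
from scipy.optimize import brentq

from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    NumericalError,
    SingularExponentError,
)
from .params import (
    ALPHA_MIN,
    MSD_DIM_FACTOR,
    ScaleDimensionProfile,
    WalkParameters,
)

__all__ = [
    "scale_dependent_dimension",
    "contour_ratio",
    "msd_normalized",
    "msd",
    "msd_ballistic",
    "msd_longtime",
    "diffusion_coefficient",
    "transport_coefficient",
    "gamma_over_D",
    "mean_velocity",
    "normalized_msd",
]

#: Relative tolerance of the implicit-equation root solve.
ROOT_RTOL = 1e-12
ROOT_MAXITER = 200


def scale_dependent_dimension(
    s: Union[float, np.ndarray], profile: ScaleDimensionProfile
) -> Union[float, np.ndarray]:
    """Trajectory fractal dimension observed at scale ``s``.

    D_w(s) = D_w - (D_w - 1)/(1 + s/(k*Lambda)); equals 1 at s = 0
    (ballistic) and approaches the asymptotic D_w for s >> k*Lambda.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise InvalidInputError("scale s must be >= 0")
    dw = profile.dw_asymptotic
    out = dw - (dw - 1.0) / (1.0 + s / (profile.k * profile.Lambda))
    return float(out) if out.ndim == 0 else out


def contour_ratio(
    r: Union[float, np.ndarray],
    params: WalkParameters,
    dw: Optional[float] = None,
) -> Union[float, np.ndarray]:
    """Displacement-to-contour-length ratio r/L(0) at displacement ``r``.

    r/L(0) = (1 + r/(k*Lambda))^(-(D_w - 1)), with Lambda the 3D mean free
    path.  L(0) is the trajectory contour length (sum of segment lengths);
    the ratio is 1 for r = 0 and for a ballistic trajectory (D_w = 1), and
    decays as the walk folds on itself.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidInputError("displacement r must be >= 0")
    if dw is None:
        dw = params.dw
    if dw < 1:
        raise InvalidParameterError(f"dw must be >= 1, got {dw}")
    out = (1.0 + r / (params.k * params.lambda_3d)) ** (-(dw - 1.0))
    return float(out) if out.ndim == 0 else out


def _solve_x(n_steps: float, alpha: float, k: float) -> float:
    """Root x >= 0 of x*(k + x)^e = k^e * n,  e = (2 - alpha)/alpha, n = t/tau.

    Solved for u = ln x (the equation is well-conditioned in log space and
    immune to overflow of (k+x)^e).  The ballistic bound gives x <= n; the
    rearrangement x = k^e n/(k + x)^e evaluated at x = n gives a lower
    bound, so the root is bracketed analytically.
    """
    if n_steps == 0.0:
        return 0.0
    e = (2.0 - alpha) / alpha
    if e == 0.0:  # alpha = 2: exact ballistic branch
        return n_steps
    log_n = math.log(n_steps)

    # after dividing by k^e: f(u) = u - ln n + e*log1p(exp(u)/k), with
    # f(ln n) = e*log1p(n/k) > 0 and f(ln n - e*log1p(n/k)) < 0 exactly
    def f(u: float) -> float:
        return u - log_n + e * math.log1p(math.exp(u) / k)

    width = e * math.log1p(n_steps / k)
    if width == 0.0:  # n/k below float resolution: ballistic to all digits
        return n_steps
    u_hi = log_n
    # extra unit of margin keeps f(u_lo) < 0 despite cancellation at tiny n
    u_lo = log_n - width - 1.0
    try:
        u = brentq(f, u_lo, u_hi, xtol=1e-300, rtol=8.9e-16, maxiter=ROOT_MAXITER)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover
        raise NumericalError(str(exc), bracket=(u_lo, u_hi)) from exc
    return math.exp(u)


def msd_normalized(
    t_over_tau: Union[float, Iterable[float]],
    alpha: float,
    k: float = 2.0,
) -> Union[float, np.ndarray]:
    """Dimensionless MSD y = <r^2>/lambda^2 after ``t_over_tau`` steps.

    x = sqrt(y) is the unique non-negative root of the implicit crossover
    equation x*(k + x)^((2-alpha)/alpha) = k^((2-alpha)/alpha) * t/tau.
    Interpolates between the ballistic limit y = (t/tau)^2 and the
    anomalous power law y = k^(2-alpha) (t/tau)^alpha.
    """
    if not (ALPHA_MIN <= alpha <= 2.0):
        raise InvalidParameterError(
            f"alpha must be in [{ALPHA_MIN}, 2], got {alpha}")
    if k <= 0:
        raise InvalidParameterError(f"k must be > 0, got {k}")
    arr = np.asarray(t_over_tau, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("t/tau must be >= 0")
    out = np.empty(arr.shape, dtype=float)
    for idx, n in np.ndenumerate(arr):
        out[idx] = _solve_x(float(n), alpha, k) ** 2
    return float(out) if out.ndim == 0 else out


def msd(
    t: Union[float, Iterable[float]],
    params: WalkParameters,
    dimensionality: int = 2,
) -> Union[float, np.ndarray]:
    """Mean square displacement at time ``t`` (length^2 units).

    The canonical solution is 2D; other dimensionalities rescale it by
    isotropy: <R^2>_3D = (3/2) <r^2>_2D, <x^2>_1D = (1/2) <r^2>_2D.
    """
    try:
        factor = MSD_DIM_FACTOR[dimensionality]
    except KeyError:
        raise InvalidParameterError(
            f"dimensionality must be 1, 2 or 3, got {dimensionality}") from None
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("time must be >= 0")
    y = msd_normalized(t_arr / params.tau, params.alpha, params.k)
    return factor * params.lambda_mfp**2 * y


def msd_ballistic(
    t: Union[float, np.ndarray], params: WalkParameters
) -> Union[float, np.ndarray]:
    """Short-time ballistic asymptote <r^2> = (lambda * t/tau)^2 = (v0 t)^2."""
    t = np.asarray(t, dtype=float)
    out = (params.lambda_mfp * t / params.tau) ** 2
    return float(out) if out.ndim == 0 else out


def msd_longtime(
    t: Union[float, np.ndarray], params: WalkParameters
) -> Union[float, np.ndarray]:
    """Long-time anomalous asymptote <r^2> = 4 * Gamma * t^alpha (2D)."""
    t = np.asarray(t, dtype=float)
    out = 4.0 * transport_coefficient(params) * t**params.alpha
    return float(out) if out.ndim == 0 else out


def diffusion_coefficient(params: WalkParameters) -> float:
    """Ordinary diffusion coefficient D = lambda^2 / (2 tau)."""
    return params.lambda_mfp**2 / (2.0 * params.tau)


def transport_coefficient(params: WalkParameters) -> float:
    """Anomalous transport coefficient Gamma (length^2/time^alpha).

    Gamma = k^(2-alpha) * lambda^2 / (4 tau^alpha); for the universal
    choice k = 2 this is the standard 2^(-alpha) lambda^2 / tau^alpha, and
    Gamma/D = (2 tau)^(1-alpha) holds exactly.
    """
    a = params.alpha
    return params.k ** (2.0 - a) * params.lambda_mfp**2 / (4.0 * params.tau**a)


def gamma_over_D(tau: float, alpha: float) -> float:
    """Ratio Gamma/D = (2 tau)^(1 - alpha).

    Multiplied by tau^(alpha-1) it collapses to the universal coordinate
    2^(1-alpha), independent of the system's characteristic time.
    """
    if tau <= 0:
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    return (2.0 * tau) ** (1.0 - alpha)


def mean_velocity(
    params: Optional[WalkParameters] = None,
    *,
    D: Optional[float] = None,
    lambda_mfp: Optional[float] = None,
    Gamma: Optional[float] = None,
    alpha: Optional[float] = None,
) -> float:
    """Mean velocity v0 of the molecule along its trajectory.

    Three equivalent parameterizations (they agree when the arguments are
    mutually consistent through D = lambda^2/2tau and the Gamma closure):

    - ``mean_velocity(params)``: v0 = lambda/tau
    - ``mean_velocity(D=..., lambda_mfp=...)``: v0 = 2D/lambda
    - ``mean_velocity(D=..., Gamma=..., alpha=...)``:
      v0 = 2 sqrt(D) (Gamma/D)^(1/(2(alpha-1))); singular at alpha = 1,
      where the 2D/lambda form must be used instead.
    """
    if params is not None:
        return params.v0
    if D is not None and lambda_mfp is not None:
        if D <= 0 or lambda_mfp <= 0:
            raise InvalidParameterError("D and lambda_mfp must be > 0")
        return 2.0 * D / lambda_mfp
    if D is not None and Gamma is not None and alpha is not None:
        if D <= 0 or Gamma <= 0:
            raise InvalidParameterError("D and Gamma must be > 0")
        if alpha == 1.0:
            raise SingularExponentError(
                "v0 from (D, Gamma, alpha) is singular at alpha = 1; "
                "use the (D, lambda_mfp) form")
        return 2.0 * math.sqrt(D) * (Gamma / D) ** (1.0 / (2.0 * (alpha - 1.0)))
    raise InvalidParameterError(
        "provide params, or (D, lambda_mfp), or (D, Gamma, alpha)")


def normalized_msd(
    t: Union[float, np.ndarray], params: WalkParameters
) -> Union[float, np.ndarray]:
    """MSD normalized by its long-time asymptote, <r^2> / (4 Gamma t^alpha).

    Rises from 0 (ballistic regime, for alpha < 2) to 1 (fully developed
    anomalous diffusion); the rise spans about three decades of t/tau and
    quantifies how advanced the crossover is at time t.
    """
    t = np.asarray(t, dtype=float)
    y = msd_normalized(t / params.tau, params.alpha, params.k)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            t > 0,
            params.k ** (params.alpha - 2.0) * y
            * np.where(t > 0, t / params.tau, 1.0) ** (-params.alpha),
            0.0,
        )
    return float(out) if out.ndim == 0 else out
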