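"""Closed-form and curve-fit estimators of the walk parameters.

The calibration chain mirrors how tracking experiments are analyzed:

1. two MSD points from ordinary (alpha = 1) diffusion give the mean free
   path lambda exactly (``estimate_lambda_two_point``);
2. the measured free diffusion coefficient then gives the step time
   tau = lambda^2/(2 D) (``tau_from_lambda_D``);
3. with (lambda, tau) fixed, the anomalous exponent alpha — and, through
   the closure Gamma = D (2 tau)^(1-alpha), the transport coefficient —
   follows from as little as one short-time MSD observation
   (``alpha_from_single_point``) or a few of them (``fit_alpha_gamma``).

For systems where anomalous and normal MSDs of the same species are
available at the same time t, the ratio-based estimators
``tau_from_anomalous_ratio`` and ``gamma_over_D_from_ratio`` recover tau
and Gamma/D without any curve fitting.  The function wrappers delegate to
the estimator classes in :mod:`fractaldiff.estimators`.
"""

from __future__ import annotations

import math

from .estimators import CalibratedMSDFit, FreeMSDFit, SinglePointMSDFit
from .exceptions import (
    DegenerateDataError,
    InconsistentDataError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    SingularExponentError,
)
from .series import FitResult, MSDSeries

__all__ = [
    "estimate_lambda_two_point",
    "tau_from_lambda_D",
    "tau_from_anomalous_ratio",
    "gamma_over_D_from_ratio",
    "alpha_from_single_point",
    "fit_alpha_gamma",
    "fit_free",
]

#: Relative tolerance below which the two-point denominator is treated as
#: zero (the two points then imply purely ballistic scaling).
_DEGENERATE_RTOL = 1e-12


def estimate_lambda_two_point(t1: float, msd1: float,
                              t2: float, msd2: float) -> float:
    """Mean free path from two ordinary-diffusion (alpha = 1) MSD points.

    lambda = ((t1/t2) * msd2/sqrt(msd1) - sqrt(msd1)) / 2
             / (1 - (t1/t2) * sqrt(msd2)/sqrt(msd1))

    Exact (not asymptotic) on model data: dividing the alpha = 1 crossover
    equation written at the two times eliminates tau.
    """
    if not (0 < t1 < t2):
        raise InvalidInputError(f"need 0 < t1 < t2, got t1={t1}, t2={t2}")
    if not (0 < msd1 < msd2):
        raise InvalidInputError(
            f"need 0 < msd1 < msd2, got msd1={msd1}, msd2={msd2}")
    s1 = math.sqrt(msd1)
    s2 = math.sqrt(msd2)
    ratio_t = t1 / t2
    denom = 1.0 - ratio_t * s2 / s1
    if abs(denom) <= _DEGENERATE_RTOL:
        raise DegenerateDataError(
            "the two points imply purely ballistic scaling "
            "(sqrt(msd) proportional to t); lambda is unidentifiable")
    lam = (ratio_t * msd2 / s1 - s1) / 2.0 / denom
    if lam <= 0:
        raise InconsistentDataError(
            f"two-point estimate gives lambda={lam:g} <= 0; the points are "
            "not consistent with sub-ballistic ordinary diffusion")
    return lam


def tau_from_lambda_D(lambda_mfp: float, D: float) -> float:
    """Brownian step time tau = lambda^2 / (2 D)."""
    if lambda_mfp <= 0 or D <= 0:
        raise InvalidParameterError("lambda_mfp and D must be > 0")
    return lambda_mfp**2 / (2.0 * D)


def tau_from_anomalous_ratio(ratio: float, alpha: float, t: float) -> float:
    """Step time from the anomalous/normal MSD ratio at a shared time t.

    tau = ratio^(1/(1-alpha)) * t/2, where ratio = <x^2>/<x^2>_Brownian is
    measured at the same time for the same species (same lambda).
    """
    if ratio <= 0:
        raise InvalidInputError(f"ratio must be > 0, got {ratio}")
    if t <= 0:
        raise InvalidInputError(f"t must be > 0, got {t}")
    if alpha == 1.0:
        raise SingularExponentError(
            "tau from the MSD ratio is singular at alpha = 1 "
            "(the ratio is then identically 1)")
    return ratio ** (1.0 / (1.0 - alpha)) * t / 2.0


def gamma_over_D_from_ratio(ratio: float, alpha: float, t: float) -> float:
    """Normalized transport coefficient Gamma/D = ratio * t^(1-alpha)."""
    if ratio <= 0:
        raise InvalidInputError(f"ratio must be > 0, got {ratio}")
    if t <= 0:
        raise InvalidInputError(f"t must be > 0, got {t}")
    return ratio * t ** (1.0 - alpha)


def alpha_from_single_point(t: float, msd: float, lambda_mfp: float,
                            tau: float, k: float = 2.0) -> FitResult:
    """Exact (alpha, Gamma) from one short-time 2D MSD observation.

    Requires sqrt(msd) < lambda * t/tau (below the ballistic bound).
    """
    est = SinglePointMSDFit(lambda_mfp=lambda_mfp, tau=tau, k=k)
    est.fit([t], [msd])
    return est.result_()


def fit_alpha_gamma(series: MSDSeries, lambda_mfp: float, tau: float,
                    k: float = 2.0) -> FitResult:
    """Least-squares alpha over an MSD series with (lambda, tau) calibrated.

    Gamma is not free: it is tied to alpha through the closure
    Gamma = 2^(-alpha) lambda^2 / tau^alpha, which is what lets short
    series pin down both transport variables.
    """
    if len(series) < 2:
        raise InsufficientDataError(
            "fit_alpha_gamma needs >= 2 points; use alpha_from_single_point")
    s2 = series.to_2d()
    est = CalibratedMSDFit(lambda_mfp=lambda_mfp, tau=tau, k=k)
    est.fit(s2.times, s2.msd)
    return est.result_()


def fit_free(series: MSDSeries, D: float, k: float = 2.0) -> FitResult:
    """Joint (alpha, Gamma) fit given only the free diffusion coefficient.

    The implied step time tau (reported in the result) should agree with
    an independently calibrated tau when the model holds.
    """
    if len(series) < 3:
        raise InsufficientDataError("fit_free needs >= 3 points")
    s2 = series.to_2d()
    est = FreeMSDFit(D=D, k=k)
    est.fit(s2.times, s2.msd)
    return est.result_()
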