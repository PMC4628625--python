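"""Synthetic MSD series and stand-in trajectories for testing estimators.

``generate_msd_series`` draws model-consistent MSD curves with
multiplicative lognormal noise (lognormal keeps MSD positive at any
coefficient of variation).  ``generate_trajectory`` builds a 2D walk of
equal segments of length lambda, one per step time tau, whose step
directions are correlated so the long-lag time-averaged MSD exponent
approaches the target alpha.  The crossover model itself prescribes no
microscopic update rule, so the trajectory generator is an explicit
STAND-IN used for fixtures and demonstrations only — its intermediate-lag
behavior is not claimed to follow the crossover equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    InsufficientSpanError,
    InvalidInputError,
    InvalidParameterError,
)
from .model import msd
from .params import WalkParameters
from .series import MSDSeries

__all__ = [
    "NoiseSpec",
    "TrajectoryTable",
    "generate_msd_series",
    "generate_trajectory",
    "msd_from_trajectory",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative noise on MSD values.

    ``cv`` is the coefficient of variation of the lognormal factor (mean
    1); ``n_replicates`` averages that many independent factors per time
    point, emulating an ensemble of tracks; ``seed`` makes the draw
    reproducible.
    """

    cv: float = 0.0
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise InvalidParameterError(f"cv must be >= 0, got {self.cv}")
        if self.n_replicates < 1:
            raise InvalidParameterError(
                f"n_replicates must be >= 1, got {self.n_replicates}")


@dataclass(frozen=True)
class TrajectoryTable:
    """Timestamped 2D positions of a single simulated track."""

    times: np.ndarray
    positions: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)
        if p.ndim != 2 or p.shape[1] != 2 or len(t) != len(p):
            raise InvalidInputError("positions must be (n, 2) matching times")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def generate_msd_series(params: WalkParameters, times: Sequence[float],
                        noise: NoiseSpec = NoiseSpec(),
                        dimensionality: int = 2) -> MSDSeries:
    """Noisy MSD series from the forward crossover model.

    Each value is msd(t_i; params) times the mean of ``n_replicates``
    lognormal factors with unit mean and the given CV; cv = 0 returns the
    exact model curve.  Fully determined by ``noise.seed``.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise InvalidInputError("all times must be > 0")
    clean = np.asarray(msd(t, params, dimensionality=dimensionality))
    if noise.cv == 0.0:
        factors = np.ones_like(clean)
    else:
        rng = np.random.default_rng(noise.seed)
        sigma2 = math.log1p(noise.cv**2)
        mu = -sigma2 / 2.0  # unit-mean lognormal
        draws = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2),
                              size=(noise.n_replicates, len(t)))
        factors = draws.mean(axis=0)
    return MSDSeries(times=t, msd=clean * factors,
                     dimensionality=dimensionality)


def _fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Gaussian noise by Davies-Harte circulant embedding."""
    if n == 1:
        return rng.standard_normal(1)
    k = np.arange(n)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    eig = np.clip(eig, 0.0, None)  # tolerate tiny negative round-off
    m = len(row)
    w = np.zeros(m, dtype=complex)
    half = m // 2
    w[0] = math.sqrt(eig[0] / m) * rng.standard_normal()
    w[half] = math.sqrt(eig[half] / m) * rng.standard_normal()
    re = rng.standard_normal(half - 1)
    im = rng.standard_normal(half - 1)
    w[1:half] = np.sqrt(eig[1:half] / (2 * m)) * (re + 1j * im)
    w[half + 1:] = np.conj(w[1:half][::-1])
    return np.fft.fft(w).real[:n]


#: Angular persistence of the alpha = 1 walk, <cos(turn)> = 1/3.  An
#: equal-step 2D walk with one-step directional memory rho has long-time
#: diffusion coefficient lambda^2 (1+rho)/(1-rho) / (4 tau); rho = 1/3
#: makes this equal the crossover model's D = lambda^2/(2 tau), so the
#: calibration chain can be exercised end to end on simulated tracks.
PERSISTENCE_ALPHA1 = 1.0 / 3.0


def generate_trajectory(params: WalkParameters, n_steps: int,
                        seed: int = 0, oversample: int = 1) -> TrajectoryTable:
    """Equal-segment 2D walk whose long-lag MSD exponent targets alpha.

    Every segment has length lambda and duration tau; ``oversample``
    positions are recorded per segment (the particle moves along each
    segment at constant speed, so oversample > 1 resolves the sub-tau
    ballistic regime).  Segment directions:

    - alpha = 2: one common direction (collinear, exactly ballistic);
    - alpha = 1: a persistent walk with wrapped-Gaussian turning angles
      of mean cosine 1/3, which matches the crossover model's long-time
      diffusion coefficient (see ``PERSISTENCE_ALPHA1``);
    - otherwise: unit-normalized pairs of fractional Gaussian noises with
      Hurst index H = alpha/2, giving power-law directional memory and a
      long-lag exponent near alpha.

    A stand-in generator — see the module docstring.
    """
    if n_steps < 2:
        raise InvalidParameterError(f"n_steps must be >= 2, got {n_steps}")
    if oversample < 1:
        raise InvalidParameterError(f"oversample must be >= 1, got {oversample}")
    rng = np.random.default_rng(seed)
    if params.alpha == 2.0:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        dirs = np.tile([math.cos(theta), math.sin(theta)], (n_steps, 1))
    elif params.alpha == 1.0:
        # <cos(eta)> = exp(-sigma^2/2) = rho for wrapped-Gaussian turns
        sigma = math.sqrt(-2.0 * math.log(PERSISTENCE_ALPHA1))
        theta = np.cumsum(rng.normal(0.0, sigma, size=n_steps))
        theta += rng.uniform(0.0, 2.0 * math.pi)
        dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    else:
        hurst = params.alpha / 2.0
        gx = _fgn(n_steps, hurst, rng)
        gy = _fgn(n_steps, hurst, rng)
        norm = np.hypot(gx, gy)
        norm[norm == 0] = 1.0
        dirs = np.column_stack([gx / norm, gy / norm])
    steps = params.lambda_mfp * dirs
    endpoints = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    if oversample == 1:
        positions = endpoints
    else:
        frac = np.arange(oversample) / oversample
        # positions along segment i: start + frac * step
        inner = endpoints[:-1, None, :] + frac[None, :, None] * steps[:, None, :]
        positions = np.vstack([inner.reshape(-1, 2), endpoints[-1]])
    dt = params.tau / oversample
    times = dt * np.arange(len(positions), dtype=float)
    return TrajectoryTable(times=times, positions=positions)


def msd_from_trajectory(traj: TrajectoryTable,
                        lags: Iterable[float]) -> MSDSeries:
    """Time-averaged MSD of a single track at the requested lag times.

    TA-MSD(lag) = mean over all start points t of |r(t+lag) - r(t)|^2.
    Lags must be positive multiples of the (uniform) sampling interval and
    smaller than the trajectory span.
    """
    lags = np.asarray(list(lags), dtype=float)
    dt = traj.dt
    span = traj.times[-1] - traj.times[0]
    steps = lags / dt
    rounded = np.rint(steps)
    if np.any(lags <= 0) or np.any(np.abs(steps - rounded) > 1e-9 * np.maximum(steps, 1.0)):
        raise InvalidInputError(
            "lags must be positive multiples of the sampling interval")
    if np.any(lags >= span + 0.5 * dt):
        raise InsufficientSpanError(
            f"largest lag {lags.max():g} exceeds trajectory span {span:g}")
    pos = traj.positions
    out = np.empty(len(lags))
    for i, mstep in enumerate(rounded.astype(int)):
        d = pos[mstep:] - pos[:-mstep]
        out[i] = float(np.mean(np.sum(d * d, axis=1)))
    return MSDSeries(times=lags, msd=out, dimensionality=2)
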