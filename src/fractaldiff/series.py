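"""Containers for MSD-versus-time data and fit results."""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .exceptions import InvalidInputError
from .params import MSD_DIM_FACTOR


@dataclass(frozen=True)
class MSDSeries:
    """An ordered mean-square-displacement table.

    ``times`` strictly increasing and positive, ``msd`` positive, equal
    length.  ``dimensionality`` records the space the displacements were
    measured in (1, 2 or 3) so fits can reduce to the canonical 2D form.
    """

    times: np.ndarray
    msd: np.ndarray
    dimensionality: int = 2
    time_unit: str = "s"
    length_unit: str = "um"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.msd, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "msd", m)
        if t.ndim != 1 or m.ndim != 1 or len(t) != len(m) or len(t) < 1:
            raise InvalidInputError("times and msd must be equal-length 1D, n >= 1")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing and > 0")
        if np.any(m <= 0):
            raise InvalidInputError("msd values must be > 0")
        if self.dimensionality not in MSD_DIM_FACTOR:
            raise InvalidInputError(
                f"dimensionality must be 1, 2 or 3, got {self.dimensionality}")

    def __len__(self) -> int:
        return len(self.times)

    def to_2d(self) -> "MSDSeries":
        """Rescale MSD values to the canonical 2D convention."""
        if self.dimensionality == 2:
            return self
        f = MSD_DIM_FACTOR[self.dimensionality]
        return replace(self, msd=self.msd / f, dimensionality=2)


@dataclass(frozen=True)
class FitResult:
    """Estimated anomalous-diffusion parameters with provenance.

    ``alpha_hat`` and ``gamma_hat`` are the anomalous exponent and transport
    coefficient; ``lambda_used``/``tau_used`` the mean free path and step
    time the fit was conditioned on (or implied, for the free fit); ``v0``
    the mean velocity; ``method`` one of single_point / least_squares /
    free_fit.  For the calibrated methods gamma_hat is tied to alpha_hat
    exactly through Gamma = 2^(-alpha) lambda^2 / tau^alpha.
    """

    alpha_hat: float
    gamma_hat: float
    lambda_used: float
    tau_used: float
    v0: float
    residual_norm: float
    n_points: int
    method: str
    at_boundary: bool = False
    flat_objective: bool = False

    def to_dict(self) -> dict:
        return {
            "alpha_hat": self.alpha_hat,
            "gamma_hat": self.gamma_hat,
            "lambda_used": self.lambda_used,
            "tau_used": self.tau_used,
            "v0": self.v0,
            "residual_norm": self.residual_norm,
            "n_points": self.n_points,
            "method": self.method,
            "at_boundary": self.at_boundary,
            "flat_objective": self.flat_objective,
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    TSV_FIELDS = ("alpha_hat", "gamma_hat", "lambda_used", "tau_used", "v0",
                  "residual_norm", "n_points", "method")

    def to_tsv(self, header: bool = True) -> str:
        """One-line TSV for shell pipelining."""
        vals = []
        for f in self.TSV_FIELDS:
            v = getattr(self, f)
            vals.append(f"{v:.12g}" if isinstance(v, float) else str(v))
        line = "\t".join(vals)
        return ("\t".join(self.TSV_FIELDS) + "\n" + line) if header else line
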