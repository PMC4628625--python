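"""Parameter containers for the fractal random-walk model.

The microscopic state of the walk is four numbers: the 2D mean free path
``lambda_mfp`` (length of one straight segment), the Brownian step time
``tau`` (duration of one segment), the anomalous diffusion exponent
``alpha`` (MSD ~ t^alpha at long times), and the crossover constant ``k``
that sets where the trajectory fractal dimension turns over from 1
(ballistic) to its asymptotic value D_w = 2/alpha.  Everything else —
diffusion coefficient D, transport coefficient Gamma, mean velocity v0 —
derives from these.

The core is unit-agnostic: the caller must use self-consistent units
(conventionally micrometres and seconds for membrane tracking data).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .exceptions import InvalidParameterError

#: Smallest anomalous exponent accepted; below this the implicit MSD
#: equation is numerically meaningless (exponent (2-alpha)/alpha blows up).
ALPHA_MIN = 0.05

#: 3D/2D mean-free-path conversion: Lambda = sqrt(3/2) * lambda.
DIM3_PATH_FACTOR = math.sqrt(1.5)

#: MSD conversion factors relative to the canonical 2D solution,
#: <R^2>_3D = (3/2) <r^2>_2D and, by isotropy, <x^2>_1D = (1/2) <r^2>_2D.
MSD_DIM_FACTOR = {1: 0.5, 2: 1.0, 3: 1.5}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class WalkParameters:
    """Microscopic parameters of the fractal walk.

    Parameters
    ----------
    lambda_mfp : float
        2D mean free path (length of one straight segment), > 0.
    tau : float
        Brownian step time (duration of one segment), > 0.
    alpha : float
        Anomalous diffusion exponent, in (ALPHA_MIN, 2]. alpha = 1 is
        ordinary diffusion, alpha = 2 ballistic motion.
    k : float
        Crossover constant of the scale-dependent fractal dimension;
        k = 2 preserves the ordinary-diffusion formula <r^2> = 4Dt and is
        the default used throughout.
    """

    lambda_mfp: float
    tau: float
    alpha: float = 1.0
    k: float = 2.0

    def __post_init__(self) -> None:
        _require(self.lambda_mfp > 0, f"lambda_mfp must be > 0, got {self.lambda_mfp}")
        _require(self.tau > 0, f"tau must be > 0, got {self.tau}")
        _require(
            ALPHA_MIN <= self.alpha <= 2.0,
            f"alpha must be in [{ALPHA_MIN}, 2], got {self.alpha}",
        )
        _require(self.k > 0, f"k must be > 0, got {self.k}")

    @property
    def dw(self) -> float:
        """Asymptotic trajectory fractal dimension D_w = 2/alpha (>= 1)."""
        return 2.0 / self.alpha

    @property
    def lambda_3d(self) -> float:
        """3D mean free path Lambda = sqrt(3/2) * lambda."""
        return DIM3_PATH_FACTOR * self.lambda_mfp

    @property
    def v0(self) -> float:
        """Mean velocity along the trajectory, v0 = lambda/tau."""
        return self.lambda_mfp / self.tau

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {"lambda": self.lambda_mfp, "tau": self.tau,
                "alpha": self.alpha, "k": self.k}

    @classmethod
    def from_dict(cls, d: dict) -> "WalkParameters":
        return cls(lambda_mfp=d["lambda"], tau=d["tau"],
                   alpha=d.get("alpha", 1.0), k=d.get("k", 2.0))

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "WalkParameters":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class ScaleDimensionProfile:
    """Specification of the scale-dependent fractal dimension curve D_w(s).

    ``dw_asymptotic`` is the large-scale trajectory fractal dimension,
    ``Lambda`` the 3D mean free path and ``k`` the crossover constant:
    D_w(s) = D_w - (D_w - 1)/(1 + s/(k*Lambda)).
    """

    dw_asymptotic: float
    k: float = 2.0
    Lambda: float = DIM3_PATH_FACTOR

    def __post_init__(self) -> None:
        _require(self.dw_asymptotic >= 1.0,
                 f"dw_asymptotic must be >= 1, got {self.dw_asymptotic}")
        _require(self.Lambda > 0, f"Lambda must be > 0, got {self.Lambda}")
        _require(self.k > 0, f"k must be > 0, got {self.k}")

    @classmethod
    def from_walk(cls, params: WalkParameters) -> "ScaleDimensionProfile":
        return cls(dw_asymptotic=params.dw, k=params.k, Lambda=params.lambda_3d)


@dataclass(frozen=True)
class DerivedCoefficients:
    """Macroscopic transport quantities derived from :class:`WalkParameters`.

    D = lambda^2/(2 tau), Gamma = 2^(-alpha) lambda^2 / tau^alpha (at k = 2),
    v0 = lambda/tau, dw = 2/alpha.  Gamma/D = (2 tau)^(1-alpha) holds exactly.
    """

    D: float
    Gamma: float
    v0: float
    dw: float

    def __post_init__(self) -> None:
        for name in ("D", "Gamma", "v0", "dw"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")

    @classmethod
    def from_walk(cls, params: WalkParameters) -> "DerivedCoefficients":
        from .model import diffusion_coefficient, transport_coefficient

        return cls(
            D=diffusion_coefficient(params),
            Gamma=transport_coefficient(params),
            v0=params.v0,
            dw=params.dw,
        )
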