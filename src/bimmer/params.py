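"""Parameter containers for the two-layer methylation HMM.

The model has three coupled binary chains per bin: ``mn`` (normal-cohort
methylation), ``mc`` (cancer-cohort methylation) and ``dm`` (differential
status, 1 when the two cohorts disagree).  Each cohort's chain carries a
categorical emission over binned read-count categories ``0..K``; the
differential chain carries no emission of its own but couples the two
methylation chains through an alpha-weighted mixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FirstLayerParams",
    "SecondLayerParams",
    "ModelParams",
    "PROB_FLOOR",
]

#: Probabilities are floored at this value before logs are taken, so that a
#: category never observed in a finite sample cannot produce -inf inside EM.
PROB_FLOOR = 1e-10

_ATOL = 1e-8


def _check_row_stochastic(mat: np.ndarray, name: str) -> None:
    if np.any(mat < -1e-15) or np.any(mat > 1 + 1e-12):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    rows = mat.sum(axis=-1)
    if not np.allclose(rows, 1.0, atol=_ATOL):
        raise ValueError(f"rows of {name} must sum to 1 (got {rows})")


def _check_prob(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


@dataclass
class FirstLayerParams:
    """One cohort's 2-state methylation HMM.

    Parameters
    ----------
    tau : float
        Probability that the first bin is methylated (state 1).
    A : (2, 2) array
        Row-stochastic transition matrix, ``A[d_prev, d] = P(d | d_prev)``.
    B : (2, K+1) array
        Row-stochastic categorical emission pmf over count categories
        ``0..K``; raw counts above ``K`` are collapsed into category ``K``.
    """

    tau: float
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.shape != (2, 2):
            raise ValueError("A must be 2x2")
        if self.B.ndim != 2 or self.B.shape[0] != 2 or self.B.shape[1] < 1:
            raise ValueError("B must have shape (2, K+1)")
        _check_prob(self.tau, "tau")
        _check_row_stochastic(self.A, "A")
        _check_row_stochastic(self.B, "B")

    @property
    def K(self) -> int:
        """Largest count category (counts above K are capped)."""
        return self.B.shape[1] - 1

    @property
    def initial_dist(self) -> np.ndarray:
        """Length-2 initial state distribution ``[P(0), P(1)]``."""
        return np.array([1.0 - self.tau, self.tau])

    def to_dict(self) -> dict:
        return {"tau": float(self.tau), "A": self.A.tolist(), "B": self.B.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FirstLayerParams":
        return cls(tau=d["tau"], A=np.asarray(d["A"]), B=np.asarray(d["B"]))


@dataclass
class SecondLayerParams:
    """Differential chain parameters Psi = {tau_dm, A_dm, alpha}.

    ``alpha`` is the convex weight blending the normal chain's own transition
    term against the hard coupling indicator in
    ``P(mn_i | mn_{i-1}, mc_i, dm_i)``.
    """

    tau_dm: float
    A_dm: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.A_dm = np.asarray(self.A_dm, dtype=float)
        if self.A_dm.shape != (2, 2):
            raise ValueError("A_dm must be 2x2")
        _check_prob(self.tau_dm, "tau_dm")
        _check_prob(self.alpha, "alpha")
        _check_row_stochastic(self.A_dm, "A_dm")

    @property
    def initial_dist(self) -> np.ndarray:
        return np.array([1.0 - self.tau_dm, self.tau_dm])

    def to_dict(self) -> dict:
        return {
            "tau_dm": float(self.tau_dm),
            "A_dm": self.A_dm.tolist(),
            "alpha": float(self.alpha),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SecondLayerParams":
        return cls(tau_dm=d["tau_dm"], A_dm=np.asarray(d["A_dm"]), alpha=d["alpha"])


@dataclass
class ModelParams:
    """Full parameter set of the two-layer model.

    ``coupling_eps`` optionally softens the hard 0/1 coupling indicator to
    ``eps``/``1-eps``; the model as defined uses the hard indicator
    (``coupling_eps = 0``).
    """

    normal: FirstLayerParams
    cancer: FirstLayerParams
    second: SecondLayerParams
    coupling_eps: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.normal.K != self.cancer.K:
            raise ValueError("normal and cancer emission matrices must share K")
        if not (0.0 <= self.coupling_eps <= 0.5):
            raise ValueError("coupling_eps must lie in [0, 0.5]")

    @property
    def K(self) -> int:
        return self.normal.K

    def to_dict(self) -> dict:
        return {
            "normal": self.normal.to_dict(),
            "cancer": self.cancer.to_dict(),
            "second": self.second.to_dict(),
            "coupling_eps": float(self.coupling_eps),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            normal=FirstLayerParams.from_dict(d["normal"]),
            cancer=FirstLayerParams.from_dict(d["cancer"]),
            second=SecondLayerParams.from_dict(d["second"]),
            coupling_eps=d.get("coupling_eps", 0.0),
        )

    def save(self, path: str | Path) -> None:
        """Serialize to JSON text; round-trips exactly (floats via repr)."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))
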