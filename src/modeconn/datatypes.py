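"""Core containers shared across the package.

A participant's parcellated fMRI record is a channels-by-time matrix
(`MultivariateSignal`); its multivariate variational mode decomposition
(MVMD) is a `ModeSet`: K narrow-band multivariate oscillatory components
("intrinsic modes") that share central frequencies across channels, plus
whatever the solver could not assign (`residual`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MultivariateSignal",
    "MVMDParams",
    "ModeSet",
    "ValidationError",
    "ParameterError",
    "SolverError",
]


class ValidationError(ValueError):
    """Raised when input data violate a documented precondition."""


class ParameterError(ValueError):
    """Raised when solver or analysis parameters are out of range."""


class SolverError(RuntimeError):
    """Raised when the iterative decomposition diverges."""


@dataclass
class MultivariateSignal:
    """One participant's C-channel, T-sample real time series.

    Parameters
    ----------
    data : ndarray, shape (C, T)
        One row per ROI / channel. Values must be finite.
    dt : float
        Sampling interval in seconds (the fMRI repetition time, TR).
    channel_labels : list of str, optional
        ROI labels; defaults to ``roi_0 .. roi_{C-1}``.
    participant_id : str
        Free-form identifier.
    """

    data: np.ndarray
    dt: float
    channel_labels: list[str] = field(default_factory=list)
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D (channels x time) array")
        C, T = self.data.shape
        if C < 1 or T < 8:
            raise ValidationError(f"need C >= 1 and T >= 8, got C={C}, T={T}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"roi_{i}" for i in range(C)]
        if len(self.channel_labels) != C:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {C} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.dt

    def demeaned(self) -> "MultivariateSignal":
        """Return a copy with each channel's mean removed (standard ingest step)."""
        out = replace(self)
        out.data = self.data - self.data.mean(axis=1, keepdims=True)
        return out


@dataclass
class MVMDParams:
    """Settings of the MVMD solver.

    ``K`` and ``alpha`` are the two scientific knobs: the number of modes
    and the bandwidth penalty (larger alpha -> narrower modes). The rest
    are numerical controls of the ADMM iteration.
    """

    K: int = 10
    alpha: float = 1000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    init: str = "log"  # log | uniform | random | zero
    seed: int = 0
    pin_first_mode_dc: bool = False
    boundary: str = "mirror"  # mirror | none

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ParameterError("K must be a positive integer")
        if self.alpha <= 0:
            raise ParameterError("alpha must be positive")
        if self.tau < 0:
            raise ParameterError("tau must be nonnegative")
        if self.tol <= 0:
            raise ParameterError("tol must be positive")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be positive")
        if self.init not in ("log", "uniform", "random", "zero"):
            raise ParameterError(f"unknown init '{self.init}'")
        if self.boundary not in ("mirror", "none"):
            raise ParameterError(f"unknown boundary '{self.boundary}'")

    def to_dict(self) -> dict:
        return {
            "K": self.K, "alpha": self.alpha, "tau": self.tau,
            "tol": self.tol, "max_iter": self.max_iter, "init": self.init,
            "seed": self.seed, "pin_first_mode_dc": self.pin_first_mode_dc,
            "boundary": self.boundary,
        }


@dataclass
class ModeSet:
    """Result of an MVMD run: K multivariate intrinsic modes.

    ``modes[k]`` is the k-th mode's (C, T) waveform; ``omega[k]`` its shared
    central frequency in Hz, sorted ascending. ``modes.sum(0) + residual``
    reproduces the decomposed input exactly by construction.
    """

    modes: np.ndarray          # (K, C, T)
    omega: np.ndarray          # (K,) Hz
    iterations: int
    converged: bool
    residual: np.ndarray       # (C, T)
    params: MVMDParams
    dt: float
    channel_labels: list[str] = field(default_factory=list)
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.modes.ndim != 3:
            raise ValidationError("modes must be (K, C, T)")
        if self.omega.shape != (self.modes.shape[0],):
            raise ValidationError("omega length must equal K")
        if np.any(self.omega < -1e-12) or np.any(self.omega > 0.5 / self.dt + 1e-9):
            raise ValidationError("omega outside [0, Nyquist]")
        if np.any(np.diff(self.omega) < -1e-12):
            warnings.warn("omega not sorted ascending", stacklevel=2)
        if not self.channel_labels:
            self.channel_labels = [f"roi_{i}" for i in range(self.modes.shape[1])]

    @property
    def K(self) -> int:
        return self.modes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.modes.shape[1]

    @property
    def n_samples(self) -> int:
        return self.modes.shape[2]

    def reconstructed(self) -> np.ndarray:
        """Sum of all modes, shape (C, T)."""
        return self.modes.sum(axis=0)

    def original(self) -> np.ndarray:
        """Decomposed input: sum of modes plus residual."""
        return self.reconstructed() + self.residual
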