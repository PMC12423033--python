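"""Mode characterisation and physiological band selection.

After decomposition, each intrinsic mode is summarised by its central
frequency, spectral bandwidth and relative energy, and classified into
the physiological bands of resting fMRI: near-DC trend/drift, the
neurophysiological band (10-200 mHz, where BOLD fluctuations of neural
origin dominate), the respiratory band (~250 mHz fundamental), the
vascular/cardiac band (~400-800 mHz, cardiac harmonic near 520 mHz) and
anything higher. Band membership is decided by the mode's global central
frequency, not by per-channel instantaneous frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ModeSet, ValidationError

__all__ = [
    "Band",
    "BandDefinitions",
    "BandProfile",
    "default_band_definitions",
    "relative_energy",
    "mode_bandwidth",
    "classify_bands",
    "select_neurophysiological",
    "band_profiles",
]

TREND = "trend"
NEURO = "neurophysiological"
RESPIRATORY = "respiratory"
VASCULAR = "vascular_cardiac"
OTHER_HIGH = "other_high"

Band = str


@dataclass(frozen=True)
class BandDefinitions:
    """Ordered, non-overlapping half-open bands covering [0, Nyquist].

    Each entry is (name, lower bound Hz inclusive, upper bound Hz
    exclusive); the last band is upper-inclusive so the cover is total.
    """

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValidationError("empty band table")
        lo_prev = None
        for name, lo, hi in self.bands:
            if hi <= lo:
                raise ValidationError(f"band '{name}' has hi <= lo")
            if lo_prev is not None and abs(lo - lo_prev) > 1e-12:
                raise ValidationError("bands must tile contiguously")
            lo_prev = hi
        if abs(self.bands[0][1]) > 1e-12:
            raise ValidationError("first band must start at 0")

    @property
    def upper_hz(self) -> float:
        return self.bands[-1][2]

    def classify(self, freq_hz: float) -> str:
        if freq_hz < 0 or freq_hz > self.upper_hz + 1e-9:
            raise ValidationError(
                f"frequency {freq_hz} Hz outside covered range "
                f"[0, {self.upper_hz}]"
            )
        for name, lo, hi in self.bands:
            if lo <= freq_hz < hi:
                return name
        return self.bands[-1][0]  # upper edge of the last band


def default_band_definitions(nyquist_hz: float = 0.5 / 0.72) -> BandDefinitions:
    """Band table for fMRI sampled at TR=0.72 s (or any Nyquist >= 0.8 Hz).

    trend [0, 10) mHz; neurophysiological [10, 200) mHz; respiratory
    [200, 350) mHz; vascular_cardiac [350, 800) mHz; other_high up to
    Nyquist. Lower bounds inclusive.
    """
    top = max(nyquist_hz, 0.8 + 1e-9)
    return BandDefinitions((
        (TREND, 0.0, 0.010),
        (NEURO, 0.010, 0.200),
        (RESPIRATORY, 0.200, 0.350),
        (VASCULAR, 0.350, 0.800),
        (OTHER_HIGH, 0.800, top),
    ))


@dataclass
class BandProfile:
    mode_index: int
    central_freq_hz: float
    bandwidth_hz: float
    rel_energy: float
    band: str


def relative_energy(ms: ModeSet) -> np.ndarray:
    """Energy fraction E_k / E_tot of each mode.

    E_k sums the squared mode waveform over channels and time; E_tot is
    the energy of the decomposed input (mode sum plus residual).
    """
    x = ms.original()
    e_tot = float(np.sum(x ** 2))
    if e_tot <= 0:
        raise ValidationError("zero-energy input signal")
    e_k = np.sum(ms.modes ** 2, axis=(1, 2))
    return e_k / e_tot


def mode_bandwidth(ms: ModeSet, k: int) -> float:
    """RMS bandwidth of mode k in Hz.

    Twice the square root of the power-weighted second central moment of
    the mode's channel-summed power spectrum about its spectral centroid.
    The factor 2 makes the value a full width; halve it to compare with a
    one-sided RMS convention.
    """
    mode = ms.modes[k]
    spec = np.fft.rfft(mode, axis=-1)
    power = (np.abs(spec) ** 2).sum(axis=0)
    total = power.sum()
    if total <= 0:
        warnings.warn(f"mode {k} has zero energy; bandwidth reported as 0",
                      stacklevel=2)
        return 0.0
    freqs = np.fft.rfftfreq(ms.n_samples, d=ms.dt)
    centroid = float((power * freqs).sum() / total)
    second = float((power * (freqs - centroid) ** 2).sum() / total)
    return 2.0 * np.sqrt(max(second, 0.0))


def classify_bands(
    central_freqs_hz: np.ndarray, defs: BandDefinitions
) -> list[str]:
    """Map each central frequency to the unique band covering it."""
    return [defs.classify(float(f)) for f in np.asarray(central_freqs_hz)]


def select_neurophysiological(
    ms: ModeSet, defs: BandDefinitions | None = None
) -> list[int]:
    """Indices of modes whose central frequency falls in 10-200 mHz.

    Returns an ascending list; empty (with a warning) when no mode
    qualifies.
    """
    if defs is None:
        defs = default_band_definitions(0.5 / ms.dt)
    labels = classify_bands(ms.omega, defs)
    idx = [k for k, b in enumerate(labels) if b == NEURO]
    if not idx:
        warnings.warn("no mode falls in the neurophysiological band",
                      stacklevel=2)
    return idx


def band_profiles(
    ms: ModeSet, defs: BandDefinitions | None = None
) -> list[BandProfile]:
    """Full per-mode summary: central frequency, bandwidth, energy, band."""
    if defs is None:
        defs = default_band_definitions(0.5 / ms.dt)
    rel = relative_energy(ms)
    labels = classify_bands(ms.omega, defs)
    return [
        BandProfile(
            mode_index=k,
            central_freq_hz=float(ms.omega[k]),
            bandwidth_hz=mode_bandwidth(ms, k),
            rel_energy=float(rel[k]),
            band=labels[k],
        )
        for k in range(ms.K)
    ]
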