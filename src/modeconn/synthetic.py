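"""Synthetic multichannel fMRI-like cohorts with known ground truth.

Real parcellated resting-state fMRI mixes, per ROI, a slow
individual-specific drift, several band-limited neural oscillations in
10-200 mHz whose spatial loadings follow the module organisation of the
brain, physiological tones (respiration ~250 mHz, cardiac harmonics
~520 mHz, possibly aliased), and broadband noise. The generator plants
exactly these ingredients with known central frequencies, loadings and
band-wise connectivity, so decomposition, band selection, FC inference
and reproducibility can all be validated against ground truth.

Waveforms are standardised to unit RMS before loading, so a component's
``amplitude`` is its per-unit-loading signal RMS and signal-to-noise
budgets are easy to state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .bands import NEURO, RESPIRATORY, TREND, VASCULAR
from .connectivity import fc_matrix
from .datatypes import MultivariateSignal, ValidationError

__all__ = [
    "ComponentSpec",
    "SyntheticSpec",
    "GroundTruth",
    "canonical_hrf",
    "block_regressor",
    "generate_cohort",
    "default_modules",
    "default_cohort_spec",
]

KIND_BAND = {
    "trend": TREND,
    "neural_oscillation": NEURO,
    "task_block": NEURO,
    "respiratory": RESPIRATORY,
    "cardiac": VASCULAR,
}


def canonical_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel, peak-normalised.

    Response gamma with shape 6 (peak 5 s), undershoot gamma with shape 16
    (trough ~15 s) weighted 1/6 — the conventional canonical
    parameterisation. ``kernel[0]`` (t = 0) is exactly 0.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    t = np.arange(0.0, duration, dt)
    peak = gamma_dist.pdf(t, a=6.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def block_regressor(
    onsets: np.ndarray | list[float],
    duration: float,
    T: int,
    dt: float,
) -> np.ndarray:
    """HRF-convolved boxcar task regressor of length T, peak-normalised."""
    onsets = np.asarray(onsets, dtype=float)
    box = np.zeros(T)
    t = np.arange(T) * dt
    for onset in onsets:
        if onset < 0 or onset >= T * dt:
            raise ValidationError(f"onset {onset}s outside the record")
        box[(t >= onset) & (t < onset + duration)] = 1.0
    if not box.any():
        return box
    reg = np.convolve(box, canonical_hrf(dt))[:T]
    peak = np.abs(reg).max()
    return reg / peak if peak > 0 else reg


@dataclass
class ComponentSpec:
    """One planted signal component.

    ``loading`` is the per-ROI spatial weight vector of the component
    (its outer product with the waveform is the planted signal); when
    ``shared_loading`` the same template is used for every participant
    (up to scalar amplitude jitter), which plants reproducible
    connectivity — otherwise the loading is redrawn per participant,
    modelling individual-specific components such as drifts.
    """

    kind: str
    center_freq_hz: float = 0.0
    amplitude: float = 1.0
    loading: np.ndarray | None = None
    shared_loading: bool = True
    freq_jitter: float = 0.10   # +/- fraction of center frequency
    amp_jitter: float = 0.20    # +/- fraction of amplitude
    block_design: tuple[list[float], float] | None = None  # (onsets s, dur s)

    def __post_init__(self) -> None:
        if self.kind not in KIND_BAND:
            raise ValidationError(f"unknown component kind '{self.kind}'")
        if self.loading is not None:
            self.loading = np.asarray(self.loading, dtype=float)
            if not np.all(np.isfinite(self.loading)):
                raise ValidationError("non-finite loadings")
        if self.kind == "task_block" and self.block_design is None:
            raise ValidationError("task_block requires block_design")


@dataclass
class SyntheticSpec:
    """Full generative description of one synthetic cohort."""

    n_participants: int = 10
    n_rois: int = 90
    dt: float = 0.72
    T: int = 1200
    modules: dict[str, list[int]] = field(default_factory=dict)
    components: list[ComponentSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0
    allow_aliasing: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.T < 64:
            raise ValidationError("T must be >= 64")
        if not self.modules:
            self.modules = default_modules(self.n_rois)
        covered = sorted(i for v in self.modules.values() for i in v)
        if covered != list(range(self.n_rois)):
            raise ValidationError("modules must partition 0..n_rois-1")

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.dt


@dataclass
class GroundTruth:
    """What was actually planted: waveforms, frequencies, band FC."""

    component_waveforms: np.ndarray      # (N, n_components, T), unit RMS
    component_loadings: np.ndarray       # (N, n_components, C)
    true_freqs: np.ndarray               # (N, n_components) Hz (0 for trend)
    band_fc: dict[str, np.ndarray]       # band -> (C, C) group-mean correlation


def default_modules(n_rois: int, n_modules: int = 7) -> dict[str, list[int]]:
    """Partition ROIs into contiguous near-equal functional modules."""
    n_modules = min(n_modules, n_rois)
    edges = np.linspace(0, n_rois, n_modules + 1).astype(int)
    return {
        f"module_{m + 1}": list(range(edges[m], edges[m + 1]))
        for m in range(n_modules)
    }


def _module_loading(
    modules: dict[str, list[int]], n_rois: int, rng: np.random.Generator
) -> np.ndarray:
    """Random module-structured loading: 2 modules active, signed weights."""
    names = list(modules)
    active = rng.choice(len(names), size=min(2, len(names)), replace=False)
    loading = np.zeros(n_rois)
    for a in active:
        loading[modules[names[a]]] = rng.choice([-1, 1]) * rng.uniform(0.7, 1.3)
    return loading


def _unit_rms(w: np.ndarray) -> np.ndarray:
    rms = float(np.sqrt(np.mean(w ** 2)))
    return w / rms if rms > 0 else w


def _trend_waveform(T: int, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Random-walk drift low-passed below 8 mHz, unit RMS."""
    walk = np.cumsum(rng.standard_normal(T))
    spec = np.fft.rfft(walk)
    freqs = np.fft.rfftfreq(T, d=dt)
    spec[freqs > 0.008] = 0.0
    w = np.fft.irfft(spec, n=T)
    w = w - w.mean()
    return _unit_rms(w)


def _tone_waveform(
    comp: ComponentSpec, T: int, dt: float, nyquist: float,
    allow_aliasing: bool, rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    f0 = comp.center_freq_hz
    if f0 > nyquist:
        if not allow_aliasing:
            raise ValidationError(
                f"component frequency {f0} Hz exceeds Nyquist {nyquist:.3f} Hz"
                " (set allow_aliasing=True to fold it in)"
            )
        folded = abs(f0 - round(f0 * 2 * dt) / (2 * dt))
        warnings.warn(
            f"{f0} Hz component aliased to {folded:.4f} Hz", stacklevel=3
        )
        f0 = folded
    f = f0 * (1.0 + rng.uniform(-comp.freq_jitter, comp.freq_jitter))
    t = np.arange(T) * dt
    phase = rng.uniform(0, 2 * np.pi)
    # gentle amplitude modulation, as in real band-limited BOLD rhythms
    am = 1.0 + 0.15 * np.sin(2 * np.pi * 0.005 * t + rng.uniform(0, 2 * np.pi))
    return _unit_rms(am * np.cos(2 * np.pi * f * t + phase)), f


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[list[MultivariateSignal], GroundTruth]:
    """Generate N participants' signals plus the planted ground truth.

    Deterministic for a fixed spec (including seed). Each participant is
    the loading-weighted sum of unit-RMS component waveforms plus white
    Gaussian noise; channels are mean-centred.
    """
    rng = np.random.default_rng(spec.seed)
    N, C, T = spec.n_participants, spec.n_rois, spec.T
    n_comp = len(spec.components)

    # shared loading templates, drawn once per cohort
    templates = []
    for comp in spec.components:
        if comp.loading is not None:
            if comp.loading.size != C:
                raise ValidationError("loading length must equal n_rois")
            templates.append(comp.loading.copy())
        elif comp.shared_loading:
            templates.append(_module_loading(spec.modules, C, rng))
        else:
            templates.append(None)  # redrawn per participant

    waveforms = np.zeros((N, n_comp, T))
    loadings = np.zeros((N, n_comp, C))
    true_freqs = np.zeros((N, n_comp))
    signals = []
    for p in range(N):
        data = np.zeros((C, T))
        for j, comp in enumerate(spec.components):
            if comp.kind == "trend":
                w, f = _trend_waveform(T, spec.dt, rng), 0.0
            elif comp.kind == "task_block":
                onsets, dur = comp.block_design
                w = _unit_rms(block_regressor(onsets, dur, T, spec.dt))
                f = comp.center_freq_hz
            else:
                w, f = _tone_waveform(
                    comp, T, spec.dt, spec.nyquist_hz,
                    spec.allow_aliasing, rng,
                )
            amp = comp.amplitude * (
                1.0 + rng.uniform(-comp.amp_jitter, comp.amp_jitter)
            )
            if templates[j] is not None:
                load = amp * templates[j]
            else:
                load = amp * rng.normal(0.0, 0.6, size=C)
            waveforms[p, j] = w
            loadings[p, j] = load
            true_freqs[p, j] = f
            data += load[:, None] * w[None, :]
        data += spec.noise_sd * rng.standard_normal((C, T))
        data -= data.mean(axis=1, keepdims=True)
        signals.append(MultivariateSignal(
            data, spec.dt, participant_id=f"sim_{p:03d}",
        ))

    band_fc = _band_ground_truth_fc(spec, waveforms, loadings)
    return signals, GroundTruth(waveforms, loadings, true_freqs, band_fc)


def _band_ground_truth_fc(
    spec: SyntheticSpec, waveforms: np.ndarray, loadings: np.ndarray
) -> dict[str, np.ndarray]:
    """Group-mean correlation of the noiseless per-band component sums."""
    out: dict[str, np.ndarray] = {}
    kinds = [c.kind for c in spec.components]
    for band in sorted({KIND_BAND[k] for k in kinds}):
        members = [j for j, k in enumerate(kinds) if KIND_BAND[k] == band]
        stack = []
        for p in range(spec.n_participants):
            sig = np.zeros((spec.n_rois, spec.T))
            for j in members:
                sig += loadings[p, j][:, None] * waveforms[p, j][None, :]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stack.append(fc_matrix(sig) if spec.n_rois >= 2 else np.ones((1, 1)))
        out[band] = np.mean(stack, axis=0)
    return out


def default_cohort_spec(
    n_participants: int = 10,
    n_rois: int = 20,
    T: int = 1200,
    dt: float = 0.72,
    seed: int = 0,
) -> SyntheticSpec:
    """Reference cohort used throughout the validation suite.

    Four planted oscillations — neural tones at 25, 60 and 110 mHz with
    module-structured loadings shared across participants, and a
    respiratory tone at 250 mHz with individual-specific loadings — plus
    an individual-specific near-DC drift and white noise at roughly unit
    signal-to-noise (0 dB) per ROI.
    """
    n_modules = 4 if n_rois < 28 else 7
    modules = default_modules(n_rois, n_modules)
    names = list(modules)

    def template(weights: dict[int, float]) -> np.ndarray:
        v = np.zeros(n_rois)
        for m, wgt in weights.items():
            v[modules[names[m % len(names)]]] = wgt
        return v

    components = [
        ComponentSpec("trend", amplitude=1.5, shared_loading=False),
        ComponentSpec("neural_oscillation", 0.025, amplitude=1.0,
                      loading=template({0: 1.0, 1: 0.8})),
        ComponentSpec("neural_oscillation", 0.060, amplitude=1.0,
                      loading=template({1: 0.9, 2: -0.8})),
        ComponentSpec("neural_oscillation", 0.110, amplitude=1.0,
                      loading=template({2: 0.7, 3: 1.0})),
        ComponentSpec("respiratory", 0.250, amplitude=0.8,
                      shared_loading=False),
    ]
    # per-ROI signal variance is ~2 with these loadings; noise_sd 1.4 puts
    # the broadband signal-to-noise ratio near 0 dB
    return SyntheticSpec(
        n_participants=n_participants, n_rois=n_rois, dt=dt, T=T,
        modules=modules, components=components, noise_sd=1.4, seed=seed,
    )
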