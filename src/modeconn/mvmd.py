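"""Multivariate variational mode decomposition (MVMD).

Decomposes a C-channel signal x(t) into K narrow-band multivariate
oscillatory components u_k(t) = [u_k,1 ... u_k,C] that share a central
frequency omega_k across channels, by minimising the summed bandwidth of
the analytic mode spectra subject to per-channel reconstruction
x_c = sum_k u_k,c. The constrained problem is solved by ADMM entirely in
the frequency domain:

* mode update — a Wiener-like filter on the nonnegative half-spectrum,
  ``u_k,c <- (x_c - sum_{j!=k} u_j,c + lam_c/2) / (1 + 2 alpha (f - f_k)^2)``;
* central-frequency update — the power-weighted spectral centroid pooled
  over ALL channels (this pooling is what makes the frequencies shared),
  ``f_k <- sum_c int f |u_k,c(f)|^2 df / sum_c int |u_k,c(f)|^2 df``;
* dual ascent ``lam <- lam + tau (x - sum_k u_k)`` (tau = 0 by default,
  which tolerates additive noise).

Internally the solver works in normalised frequency (cycles/sample,
Nyquist = 0.5); central frequencies are reported in Hz.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import hilbert

from .datatypes import (
    ModeSet,
    MultivariateSignal,
    MVMDParams,
    ParameterError,
    SolverError,
    ValidationError,
)

__all__ = [
    "analytic_signal",
    "mvmd_decompose",
    "reconstruct",
    "instantaneous_attributes",
]


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Discrete analytic signal of a real vector.

    The real part equals the input exactly; the imaginary part is the
    discrete Hilbert transform, so the spectrum has (approximately) no
    negative-frequency content.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("analytic_signal expects a 1-D vector, T >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("analytic_signal: non-finite input")
    # keep the real part bitwise equal to the input; the FFT round-trip
    # inside hilbert() would otherwise perturb it at machine precision
    return x + 1j * hilbert(x).imag


def _mirror_extend(data: np.ndarray) -> tuple[np.ndarray, slice]:
    """Mirror-extend each channel by T//2 samples on both sides.

    Reduces edge ringing of the spectral filtering; the returned slice
    crops the extension off again.
    """
    T = data.shape[-1]
    half = T // 2
    left = data[..., :half][..., ::-1]
    right = data[..., half:][..., ::-1]
    return np.concatenate([left, data, right], axis=-1), slice(half, half + T)


def _init_omega(K: int, init: str, seed: int, T: int) -> np.ndarray:
    # normalised frequency, cycles/sample
    if init == "log":
        # one near-DC center plus K-1 geometrically spaced centers up to
        # Nyquist/2: physiological spectra are 1/f-like and the central
        # frequencies of fMRI modes are roughly geometrically spaced, so a
        # log grid seeds the crowded low end densely enough to keep slow
        # oscillations from being absorbed into the drift mode
        if K == 1:
            return np.zeros(1)
        f_lo = min(5.0 / T, 0.05)  # a few DFT bins of the original record
        centers = np.geomspace(f_lo, 0.25, K)
        centers[0] = 0.0
        return centers
    if init == "uniform":
        # evenly spaced over the lower half of the band [0, Nyquist/2]
        return 0.25 * np.arange(K) / K
    if init == "random":
        rng = np.random.default_rng(seed)
        return np.sort(rng.uniform(0.0, 0.5, size=K))
    return np.zeros(K)


def mvmd_decompose(signal: MultivariateSignal, params: MVMDParams) -> ModeSet:
    """Run the ADMM solver and return a finalized :class:`ModeSet`.

    Deterministic for a fixed seed and init. Modes are sorted by ascending
    central frequency; the residual is defined as input minus the mode sum,
    so ``modes + residual`` reproduces the input to machine precision.
    """
    x = signal.data
    C, T = x.shape
    if params.K > T // 4:
        raise ParameterError(
            f"K={params.K} too large for T={T} samples (need K <= T/4)"
        )
    if np.allclose(x, x[:, :1]) and params.K >= 2:
        warnings.warn(
            "all-constant input with K >= 2: modes will duplicate near DC",
            stacklevel=2,
        )

    if params.boundary == "mirror":
        xe, crop = _mirror_extend(x)
    else:
        xe, crop = x, slice(0, T)
    Te = xe.shape[-1]

    X = np.fft.rfft(xe, axis=-1)            # (C, F) nonnegative half-spectrum
    F = X.shape[-1]
    f = np.fft.rfftfreq(Te)                 # normalised frequency grid

    omega = _init_omega(params.K, params.init, params.seed, T)
    U = np.zeros((params.K, C, F), dtype=complex)   # mode half-spectra
    lam = np.zeros((C, F), dtype=complex)           # Lagrange multipliers
    sum_U = U.sum(axis=0)

    alpha = params.alpha
    n_iter = 0
    converged = False
    for n_iter in range(1, params.max_iter + 1):
        diff = 0.0
        for k in range(params.K):
            sum_others = sum_U - U[k]
            num = X - sum_others + lam / 2.0
            filt = 1.0 / (1.0 + 2.0 * alpha * (f - omega[k]) ** 2)
            new_uk = num * filt
            power = np.abs(new_uk) ** 2
            denom = power.sum()
            if not (k == 0 and params.pin_first_mode_dc):
                if denom > 0:
                    omega[k] = float((power * f).sum() / denom)
            old_norm = np.abs(U[k]) ** 2
            old = old_norm.sum()
            if old > 0:
                diff += float((np.abs(new_uk - U[k]) ** 2).sum() / old)
            else:
                diff += float(denom)
            sum_U = sum_others + new_uk
            U[k] = new_uk
        if params.tau > 0:
            lam = lam + params.tau * (X - sum_U)
        if not np.all(np.isfinite(sum_U.view(float))):
            raise SolverError(f"solver diverged at iteration {n_iter}")
        if diff < params.tol:
            converged = True
            break

    # a mode that captured no energy has a meaningless center; report it at DC
    mode_power = (np.abs(U) ** 2).sum(axis=(1, 2))
    omega[mode_power == 0] = 0.0

    order = np.argsort(omega, kind="stable")
    omega = omega[order]
    U = U[order]

    # collision warning: centers closer than one frequency bin
    if params.K > 1 and np.any(np.diff(omega) < 1.0 / Te):
        warnings.warn(
            "two mode central frequencies collided within one frequency bin; "
            "both kept", stacklevel=2,
        )

    modes = np.empty((params.K, C, T))
    for k in range(params.K):
        modes[k] = np.fft.irfft(U[k], n=Te, axis=-1)[:, crop]
    residual = x - modes.sum(axis=0)

    return ModeSet(
        modes=modes,
        omega=omega / signal.dt,
        iterations=n_iter,
        converged=converged,
        residual=residual,
        params=params,
        dt=signal.dt,
        channel_labels=list(signal.channel_labels),
        participant_id=signal.participant_id,
    )


def reconstruct(ms: ModeSet) -> np.ndarray:
    """Sum of all modes (the solver's approximation of the input)."""
    return ms.reconstructed()


def instantaneous_attributes(
    mode: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel instantaneous amplitude and frequency of a mode.

    Amplitude is the modulus of the analytic signal; frequency is the
    time derivative of the unwrapped analytic phase scaled to Hz and
    clipped to [0, Nyquist]. Channels with (near-)zero amplitude report
    frequency 0 by convention.
    """
    mode = np.asarray(mode, dtype=float)
    if mode.ndim == 1:
        mode = mode[None, :]
    if mode.shape[-1] < 4:
        raise ValidationError("instantaneous_attributes needs T >= 4")
    analytic = hilbert(mode, axis=-1)
    amplitude = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic), axis=-1)
    freq = np.gradient(phase, axis=-1) / (2.0 * np.pi * dt)
    freq = np.clip(freq, 0.0, 0.5 / dt)
    tiny = 1e-12 * max(1.0, float(amplitude.max(initial=0.0)))
    freq[amplitude <= tiny] = 0.0
    return amplitude, freq
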