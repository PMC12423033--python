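"""Independent univariate variational mode decomposition oracle.

A from-scratch, single-channel implementation of the frequency-domain
ADMM scheme (Wiener-like mode update, power-centroid frequency update,
optional dual ascent), written directly against the update equations
without importing anything from the package under test. Used to check
that the multivariate solver collapses to the univariate one at C=1.
"""

from __future__ import annotations

import numpy as np


def univariate_vmd(
    x: np.ndarray,
    K: int,
    alpha: float,
    tau: float = 0.0,
    tol: float = 1e-7,
    max_iter: int = 500,
    mirror: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a 1-D signal; returns (modes (K, T), omega (K,) cycles/sample).

    Initialisation mirrors the package default: K log-spaced centers
    between 5/T and 0.25 with the first replaced by DC.
    """
    x = np.asarray(x, dtype=float)
    T = x.size

    if mirror:
        half = T // 2
        ext = np.concatenate([x[:half][::-1], x, x[half:][::-1]])
        lo, hi = half, half + T
    else:
        ext, lo, hi = x, 0, T
    Te = ext.size

    X = np.fft.rfft(ext)
    freqs = np.fft.rfftfreq(Te)

    if K == 1:
        omega = np.zeros(1)
    else:
        omega = np.geomspace(min(5.0 / T, 0.05), 0.25, K)
        omega[0] = 0.0
    U = np.zeros((K, X.size), dtype=complex)
    lam = np.zeros(X.size, dtype=complex)

    for _ in range(max_iter):
        diff = 0.0
        for k in range(K):
            others = np.zeros_like(X)
            for j in range(K):
                if j != k:
                    others = others + U[j]
            new = (X - others + lam / 2.0) / (
                1.0 + 2.0 * alpha * (freqs - omega[k]) ** 2
            )
            p = np.abs(new) ** 2
            if p.sum() > 0:
                omega[k] = float((p * freqs).sum() / p.sum())
            old_p = (np.abs(U[k]) ** 2).sum()
            if old_p > 0:
                diff += float((np.abs(new - U[k]) ** 2).sum() / old_p)
            else:
                diff += float(p.sum())
            U[k] = new
        if tau > 0:
            total = np.zeros_like(X)
            for k in range(K):
                total = total + U[k]
            lam = lam + tau * (X - total)
        if diff < tol:
            break

    power = (np.abs(U) ** 2).sum(axis=1)
    omega[power == 0] = 0.0
    order = np.argsort(omega, kind="stable")
    omega = omega[order]
    U = U[order]
    modes = np.stack([np.fft.irfft(U[k], n=Te)[lo:hi] for k in range(K)])
    return modes, omega
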