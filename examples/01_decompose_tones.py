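"""Decompose a known multichannel tone mixture into intrinsic modes.

Builds an 8-channel signal mixing tones at 20, 100 and 250 mHz (sampled
at TR = 0.72 s, as in fast resting-state fMRI), runs the multivariate
decomposition with K = 3 and alpha = 1000, and prints the recovered
central frequencies and reconstruction error. The central frequencies
should land within a few percent of the planted ones.
"""

import numpy as np

from modeconn import MultivariateSignal, MVMDParams, mvmd_decompose, reconstruct

DT, T = 0.72, 1200
TONES = [0.020, 0.100, 0.250]  # Hz

rng = np.random.default_rng(0)
t = np.arange(T) * DT
data = np.zeros((8, T))
for c in range(8):
    for f, phase in zip(TONES, rng.uniform(0, 2 * np.pi, 3)):
        data[c] += rng.uniform(0.5, 1.5) * np.cos(2 * np.pi * f * t + phase)

signal = MultivariateSignal(data, dt=DT)
ms = mvmd_decompose(signal, MVMDParams(K=3, alpha=1000))

print("planted frequencies (Hz):", TONES)
print("recovered omega (Hz):    ", np.round(ms.omega, 4))
rel_err = np.abs(ms.omega - TONES) / np.array(TONES)
print("relative error (%):      ", np.round(100 * rel_err, 2))
rec = reconstruct(ms)
print("reconstruction rel. L2:  ",
      f"{np.linalg.norm(data - rec) / np.linalg.norm(data):.4f}")
print("converged:", ms.converged, "after", ms.iterations, "iterations")
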