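"""Cross-participant reproducibility of per-mode FC patterns.

Two participants' FC matrices for the same mode are compared by Pearson
correlation of their vectorized upper triangles; doing this for every
unordered pair of participants yields N(N-1)/2 similarity values whose
distribution summarises how consistent that mode's connectivity is
across individuals. Modes are matched across participants by index
after the ascending-frequency sort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ValidationError

__all__ = ["ReproducibilityResult", "vectorize_upper", "pairwise_similarity"]


@dataclass
class ReproducibilityResult:
    mode_index: int
    pair_similarities: np.ndarray  # (N(N-1)/2,) possibly with NaN
    median: float
    q1: float
    q3: float
    mean: float

    @property
    def n_pairs(self) -> int:
        return self.pair_similarities.size


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Row-major upper triangle (excluding diagonal) of a symmetric matrix.

    Order: (0,1), (0,2), ..., (0,C-1), (1,2), ... — the order produced by
    ``numpy.triu_indices(C, k=1)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError("expected a square matrix")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValidationError("matrix is not symmetric")
    C = matrix.shape[0]
    return matrix[np.triu_indices(C, k=1)]


def pairwise_similarity(
    fc_stack: np.ndarray, mode_index: int = 0
) -> ReproducibilityResult:
    """All-pairs Pearson similarity of participants' FC matrices.

    ``fc_stack`` is (N, C, C); returns the N(N-1)/2 pair correlations and
    their summary. Pairs involving a participant whose FC vector is
    constant are NaN and excluded from the summary (with a warning).
    """
    fc_stack = np.asarray(fc_stack, dtype=float)
    if fc_stack.ndim != 3 or fc_stack.shape[1] != fc_stack.shape[2]:
        raise ValidationError("fc_stack must be (N, C, C)")
    N = fc_stack.shape[0]
    if N < 2:
        raise ValidationError("need N >= 2 participants")

    C = fc_stack.shape[1]
    iu = np.triu_indices(C, k=1)
    vectors = fc_stack[:, iu[0], iu[1]]          # (N, E)
    sd = vectors.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} participant(s) have constant FC vectors; "
            "their pairs reported as NaN", stacklevel=2,
        )
    d = vectors - vectors.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(d, axis=1)
    norm[constant] = 1.0
    d = d / norm[:, None]
    r = d @ d.T
    r[constant, :] = np.nan
    r[:, constant] = np.nan

    pi, pj = np.triu_indices(N, k=1)
    sims = np.clip(r[pi, pj], -1.0, 1.0)
    finite = sims[np.isfinite(sims)]
    if finite.size:
        median, q1, q3 = np.percentile(finite, [50, 25, 75])
        mean = float(finite.mean())
    else:
        median = q1 = q3 = mean = float("nan")
    return ReproducibilityResult(
        mode_index=mode_index,
        pair_similarities=sims,
        median=float(median), q1=float(q1), q3=float(q3), mean=mean,
    )
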