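"""Per-mode static functional connectivity with permutation significance.

For each selected intrinsic mode, Pearson correlation between channel
waveforms gives a C x C FC matrix per participant; Fisher-Z transforming
stabilises the variance for averaging and testing. Significance is
assessed against a null built by independently permuting the temporal
samples of each channel of the mode — independent shuffles per channel
destroy all cross-channel alignment while preserving each channel's
amplitude distribution (a shared shuffle would preserve the correlations
and produce a degenerate null). Edge-wise observed-vs-null contrasts use
a label-permutation Welch t-test with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datatypes import ModeSet, ParameterError, ValidationError

__all__ = [
    "FCResult",
    "ModuleOrdering",
    "fc_matrix",
    "fisher_z",
    "build_null",
    "group_significance",
    "average_fc",
    "order_by_module",
    "composite_matrix",
    "mode_fc_analysis",
]

_R_CLIP = 1.0 - 1e-7


def fc_matrix(mode: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a (C, T) waveform, rows = channels.

    Symmetric with unit diagonal. Rows/columns of constant channels are
    set to 0 (diagonal kept at 1) with a warning.
    """
    mode = np.asarray(mode, dtype=float)
    if mode.ndim != 2 or mode.shape[0] < 2:
        raise ValidationError("fc_matrix expects a (C>=2, T) matrix")
    if mode.shape[1] < 3:
        raise ValidationError("fc_matrix needs T >= 3")
    sd = mode.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mode)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant channel(s); their correlations "
            "set to 0", stacklevel=2,
        )
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher-Z transform atanh(r); |r|=1 is clipped to 1 - 1e-7 first."""
    r = np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _z_offdiag(mode: np.ndarray) -> np.ndarray:
    z = fisher_z(fc_matrix(mode))
    np.fill_diagonal(z, 0.0)
    return z


def _batched_corr(stack: np.ndarray) -> np.ndarray:
    """Correlation matrices for a (P, C, T) stack, constant rows -> 0."""
    d = stack - stack.mean(axis=-1, keepdims=True)
    norm = np.sqrt((d ** 2).sum(axis=-1))
    bad = norm == 0
    norm[bad] = 1.0
    d /= norm[..., None]
    r = np.einsum("pct,pdt->pcd", d, d)
    if bad.any():
        for p, c in zip(*np.nonzero(bad)):
            r[p, c, :] = 0.0
            r[p, :, c] = 0.0
    return np.clip(r, -1.0, 1.0)


def build_null(
    ms: ModeSet, mode_index: int, n_perm: int, seed: int
) -> np.ndarray:
    """Null Fisher-Z FC matrices from temporally shuffled mode waveforms.

    Each of the ``n_perm`` draws applies an independent random
    permutation of time indices to every channel of the selected mode,
    then computes the Fisher-Z FC matrix. Deterministic given ``seed``;
    diagonals are set to 0.
    """
    if n_perm <= 0:
        raise ParameterError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null", stacklevel=2)
    mode = ms.modes[mode_index]
    rng = np.random.default_rng(seed)
    shuffled = np.broadcast_to(mode, (n_perm,) + mode.shape).copy()
    rng.permuted(shuffled, axis=-1, out=shuffled)
    z = fisher_z(_batched_corr(shuffled))
    for p in range(n_perm):
        np.fill_diagonal(z[p], 0.0)
    return z


def group_significance(
    per_participant_z: np.ndarray,
    nulls: np.ndarray,
    q: float = 0.001,
    n_stat_perm: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Edge-wise permutation t-test against the pooled null, BH-corrected.

    For every off-diagonal edge a two-sided Welch t statistic contrasts
    the N observed Fisher-Z values with all pooled null values; its
    p-value is the tail fraction of ``n_stat_perm`` label-shuffled
    statistics with continuity correction p = (b+1)/(n+1).
    Benjamini-Hochberg step-up at level ``q`` over the C(C-1)/2 upper
    triangle edges yields a symmetric boolean mask (diagonal False).
    Edges that are identically constant across observed and null values
    (e.g. from constant channels) are excluded and reported False.
    """
    obs = np.asarray(per_participant_z, dtype=float)
    nul = np.asarray(nulls, dtype=float)
    if obs.ndim != 3:
        raise ValidationError("per_participant_z must be (N, C, C)")
    N, C, _ = obs.shape
    if N < 2:
        raise ValidationError("need N >= 2 participants")
    if not (0.0 < q < 1.0):
        raise ParameterError("q must lie in (0, 1)")
    if n_stat_perm <= 0:
        raise ParameterError("n_stat_perm must be positive")
    if nul.ndim == 4:
        nul = nul.reshape(-1, C, C)  # pool permutations across participants

    iu, ju = np.triu_indices(C, k=1)
    obs_e = obs[:, iu, ju]                    # (N, E)
    nul_e = nul[:, iu, ju]                    # (M, E)
    E = obs_e.shape[1]
    values = np.concatenate([obs_e, nul_e], axis=0)     # (N+M, E)
    M_tot = values.shape[0]

    testable = values.std(axis=0) > 0
    t_obs = _welch_t(obs_e, nul_e)

    rng = np.random.default_rng(seed)
    # one set of label permutations shared across edges
    exceed = np.zeros(E)
    chunk = 500
    for start in range(0, n_stat_perm, chunk):
        n_c = min(chunk, n_stat_perm - start)
        # random N-subsets as "observed" labels; argpartition of random
        # keys is O(M) per draw vs O(M log M) for a full sort
        idx = np.argpartition(
            rng.random((n_c, M_tot)), N, axis=1
        )[:, :N]                                     # (n_c, N) "observed" draws
        ga = values[idx, :]                          # (n_c, N, E)
        t_perm = _welch_t_vs_rest(ga, values)
        exceed += (np.abs(t_perm) >= np.abs(t_obs)[None, :]).sum(axis=0)
    pvals = (exceed + 1.0) / (n_stat_perm + 1.0)
    pvals[~testable] = 1.0

    reject = np.zeros(E, dtype=bool)
    if testable.any():
        reject[testable] = multipletests(
            pvals[testable], alpha=q, method="fdr_bh"
        )[0]
    mask = np.zeros((C, C), dtype=bool)
    mask[iu, ju] = reject
    return mask | mask.T


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    denom[denom == 0] = np.inf
    return (a.mean(axis=0) - b.mean(axis=0)) / denom


def _welch_t_vs_rest(ga: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Welch t of drawn groups (n_c, N, E) vs their complements in values."""
    n_c, N, E = ga.shape
    M_tot = values.shape[0]
    nb = M_tot - N
    tot_s = values.sum(axis=0)
    tot_ss = (values ** 2).sum(axis=0)
    sa = ga.sum(axis=1)
    ssa = (ga ** 2).sum(axis=1)
    ma = sa / N
    mb = (tot_s - sa) / nb
    va = (ssa - N * ma ** 2) / (N - 1)
    vb = (tot_ss - ssa - nb * mb ** 2) / (nb - 1)
    va = np.maximum(va, 0.0)
    vb = np.maximum(vb, 0.0)
    denom = np.sqrt(va / N + vb / nb)
    denom[denom == 0] = np.inf
    return (ma - mb) / denom


def average_fc(per_participant_z: np.ndarray) -> np.ndarray:
    """Elementwise mean of a stack of Fisher-Z matrices."""
    z = np.asarray(per_participant_z, dtype=float)
    if z.ndim != 3 or z.shape[0] < 1:
        raise ValidationError("expected an (N>=1, C, C) stack")
    return z.mean(axis=0)


@dataclass
class ModuleOrdering:
    """Permutation that groups ROIs of the same functional module together."""

    roi_labels: list[str]
    module_of: dict[str, str]
    ordered_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = [l for l in self.roi_labels if l not in self.module_of]
        if missing:
            raise ValidationError(f"ROIs without module assignment: {missing}")
        if self.ordered_indices is None:
            seen: list[str] = []
            for l in self.roi_labels:
                m = self.module_of[l]
                if m not in seen:
                    seen.append(m)
            order = [
                i for m in seen
                for i, l in enumerate(self.roi_labels)
                if self.module_of[l] == m
            ]
            self.ordered_indices = np.asarray(order, dtype=int)
        else:
            self.ordered_indices = np.asarray(self.ordered_indices, dtype=int)
            if sorted(self.ordered_indices) != list(range(len(self.roi_labels))):
                raise ValidationError("ordered_indices is not a permutation")

    @property
    def ordered_labels(self) -> list[str]:
        return [self.roi_labels[i] for i in self.ordered_indices]

    def inverse(self) -> np.ndarray:
        inv = np.empty_like(self.ordered_indices)
        inv[self.ordered_indices] = np.arange(len(self.ordered_indices))
        return inv


def order_by_module(matrix: np.ndarray, ordering: ModuleOrdering) -> np.ndarray:
    """Simultaneous row/column permutation grouping modules contiguously."""
    matrix = np.asarray(matrix)
    ix = ordering.ordered_indices
    if matrix.shape[0] != ix.size or matrix.shape[1] != ix.size:
        raise ValidationError("matrix size does not match ordering")
    return matrix[np.ix_(ix, ix)]


def composite_matrix(
    group_mean_z: np.ndarray, significant: np.ndarray
) -> np.ndarray:
    """Display matrix: lower triangle all mean-Z values, upper triangle only
    the significant ones (non-significant entries zeroed), diagonal zero."""
    C = group_mean_z.shape[0]
    out = np.zeros_like(group_mean_z)
    il = np.tril_indices(C, k=-1)
    iu = np.triu_indices(C, k=1)
    out[il] = group_mean_z[il]
    out[iu] = np.where(significant[iu], group_mean_z[iu], 0.0)
    return out


@dataclass
class FCResult:
    """Per-mode FC across a cohort with group mean and significance mask."""

    mode_index: int
    per_participant_z: np.ndarray  # (N, C, C)
    group_mean_z: np.ndarray       # (C, C)
    significant: np.ndarray        # (C, C) bool
    q_threshold: float = 0.001
    n_permutations: int = 0


def mode_fc_analysis(
    mode_sets: list[ModeSet],
    mode_indices: list[int],
    n_perm: int = 200,
    q: float = 0.001,
    n_stat_perm: int = 10_000,
    seed: int = 0,
) -> list[FCResult]:
    """Full Step-IV analysis: per-mode FC, group mean and significance.

    ``mode_sets`` holds one decomposition per participant (modes matched
    across participants by index after ascending-frequency sort).
    """
    if len(mode_sets) < 2:
        raise ValidationError("need at least 2 participants")
    results = []
    for j, k in enumerate(mode_indices):
        z_stack = np.stack([_z_offdiag(ms.modes[k]) for ms in mode_sets])
        nulls = np.stack([
            build_null(ms, k, n_perm, seed=seed + 1000 * j + i)
            for i, ms in enumerate(mode_sets)
        ])
        sig = group_significance(
            z_stack, nulls, q=q, n_stat_perm=n_stat_perm,
            seed=seed + 500_000 + j,
        )
        results.append(FCResult(
            mode_index=k,
            per_participant_z=z_stack,
            group_mean_z=average_fc(z_stack),
            significant=sig,
            q_threshold=q,
            n_permutations=n_perm,
        ))
    return results
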