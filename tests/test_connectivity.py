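import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from modeconn.connectivity import (
    ModuleOrdering,
    average_fc,
    build_null,
    composite_matrix,
    fc_matrix,
    fisher_z,
    group_significance,
    order_by_module,
)
from modeconn.datatypes import (
    ModeSet,
    MVMDParams,
    ParameterError,
    ValidationError,
)

from conftest import DT


def modeset_from(mode: np.ndarray) -> ModeSet:
    mode = np.asarray(mode, dtype=float)
    return ModeSet(
        modes=mode[None], omega=np.array([0.05]), iterations=1,
        converged=True, residual=np.zeros_like(mode),
        params=MVMDParams(K=1), dt=DT,
    )


class TestFCMatrix:
    def test_identical_channels_fully_correlated(self):
        x = np.random.default_rng(0).standard_normal(200)
        r = fc_matrix(np.stack([x, x]))
        assert r[0, 1] == pytest.approx(1.0)

    def test_negated_channel_anticorrelated(self):
        x = np.random.default_rng(0).standard_normal(200)
        r = fc_matrix(np.stack([x, -x]))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_independent_channels_near_zero(self):
        data = np.random.default_rng(42).standard_normal((10, 10_000))
        r = fc_matrix(data)
        off = r[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_output_contract(self):
        data = np.random.default_rng(1).standard_normal((5, 300))
        r = fc_matrix(data)
        assert np.allclose(r, r.T, atol=1e-12)
        assert np.allclose(np.diag(r), 1.0)
        assert np.all(np.abs(r) <= 1.0)

    def test_constant_channel_zeroed_with_warning(self):
        data = np.random.default_rng(2).standard_normal((3, 100))
        data[1] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            r = fc_matrix(data)
        assert np.all(r[1, [0, 2]] == 0) and r[1, 1] == 1.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            fc_matrix(np.zeros((3, 2)))


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    @given(st.floats(-1.0, 1.0))
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_unit_correlation_clipped_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))


class TestBuildNull:
    def _planted(self, seed=0, C=6, T=1200, r=0.8):
        rng = np.random.default_rng(seed)
        shared = rng.standard_normal(T)
        data = r * shared + np.sqrt(1 - r ** 2) * rng.standard_normal((C, T))
        return modeset_from(data)

    def test_shuffling_destroys_planted_correlation(self):
        ms = self._planted()
        nulls = build_null(ms, 0, n_perm=200, seed=1)
        off = ~np.eye(ms.n_channels, dtype=bool)
        assert np.abs(nulls[:, off].mean()) < 0.05
        # sanity: the observed data really are strongly correlated
        assert fc_matrix(ms.modes[0])[0, 1] > 0.5

    def test_same_seed_reproduces_null(self):
        ms = self._planted()
        a = build_null(ms, 0, 50, seed=9)
        b = build_null(ms, 0, 50, seed=9)
        assert np.array_equal(a, b)

    def test_nonpositive_n_perm_rejected(self):
        with pytest.raises(ParameterError):
            build_null(self._planted(), 0, 0, seed=0)

    def test_small_case_variance_matches_enumeration(self):
        """C=2, T=4: empirical null variance vs all (4!)^2 shuffle pairs."""
        mode = np.array([[0.3, -1.2, 0.7, 1.9], [0.5, 2.0, -0.4, -1.1]])
        zs = []
        for pa in itertools.permutations(range(4)):
            for pb in itertools.permutations(range(4)):
                r = np.corrcoef(mode[0, list(pa)], mode[1, list(pb)])[0, 1]
                zs.append(fisher_z(r))
        exact_var = np.var(zs)
        ms = modeset_from(mode)
        nulls = build_null(ms, 0, n_perm=4000, seed=3)
        emp_var = nulls[:, 0, 1].var()
        assert abs(emp_var - exact_var) / exact_var < 0.25


class TestGroupSignificance:
    def _observed_and_null(self, seed, N=8, C=6, T=600, edge=None, r=0.7):
        rng = np.random.default_rng(seed)
        z_stack, nulls = [], []
        for i in range(N):
            data = rng.standard_normal((C, T))
            if edge is not None:
                a, b = edge
                shared = rng.standard_normal(T)
                data[a] = r * shared + np.sqrt(1 - r ** 2) * rng.standard_normal(T)
                data[b] = r * shared + np.sqrt(1 - r ** 2) * rng.standard_normal(T)
            ms = modeset_from(data)
            z = fisher_z(fc_matrix(data))
            np.fill_diagonal(z, 0.0)
            z_stack.append(z)
            nulls.append(build_null(ms, 0, 60, seed=seed + i + 1))
        return np.stack(z_stack), np.stack(nulls)

    def test_planted_edge_detected_others_not(self):
        # Benjamini-Hochberg at level q over E edges can only reject a lone
        # true edge if min p = 1/(n_stat_perm+1) <= q/E, hence 2000 draws here
        obs, nulls = self._observed_and_null(0, edge=(0, 1))
        mask = group_significance(obs, nulls, q=0.01, n_stat_perm=2000, seed=5)
        assert mask[0, 1] and mask[1, 0]
        assert mask.sum() <= 4  # at most the planted edge plus one stray

    def test_mask_symmetric_diagonal_false(self):
        obs, nulls = self._observed_and_null(1, edge=(2, 3))
        mask = group_significance(obs, nulls, q=0.01, n_stat_perm=300, seed=2)
        assert np.array_equal(mask, mask.T)
        assert not mask.diagonal().any()

    def test_deterministic_given_seed(self):
        obs, nulls = self._observed_and_null(2, edge=(0, 2))
        a = group_significance(obs, nulls, q=0.01, n_stat_perm=300, seed=7)
        b = group_significance(obs, nulls, q=0.01, n_stat_perm=300, seed=7)
        assert np.array_equal(a, b)

    def test_single_participant_rejected(self):
        obs, nulls = self._observed_and_null(3)
        with pytest.raises(ValidationError):
            group_significance(obs[:1], nulls[:1], q=0.01, n_stat_perm=10)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.5])
    def test_invalid_q_rejected(self, q):
        obs, nulls = self._observed_and_null(4)
        with pytest.raises(ParameterError):
            group_significance(obs, nulls, q=q, n_stat_perm=10)


class TestAverageFC:
    def test_identical_matrices(self):
        m = np.random.default_rng(0).standard_normal((4, 4))
        m = m + m.T
        assert np.allclose(average_fc(np.stack([m] * 5)), m)

    def test_opposite_matrices_cancel(self):
        m = np.random.default_rng(1).standard_normal((4, 4))
        assert np.allclose(average_fc(np.stack([m, -m])), 0.0)

    def test_matches_manual_mean(self):
        stack = np.random.default_rng(2).standard_normal((7, 5, 5))
        expected = sum(stack[i] for i in range(7)) / 7
        assert np.allclose(average_fc(stack), expected, atol=1e-12)


class TestModuleOrdering:
    def test_identity_ordering_is_noop(self):
        labels = ["a", "b", "c"]
        ordering = ModuleOrdering(labels, {l: "m1" for l in labels})
        m = np.arange(9.0).reshape(3, 3)
        assert np.array_equal(order_by_module(m, ordering), m)

    def test_inverse_recovers_original(self):
        rng = np.random.default_rng(0)
        labels = [f"r{i}" for i in range(6)]
        module_of = {l: f"m{i % 3}" for i, l in enumerate(labels)}
        ordering = ModuleOrdering(labels, module_of)
        m = rng.standard_normal((6, 6))
        m = m + m.T
        ordered = order_by_module(m, ordering)
        inv = ordering.inverse()
        assert np.array_equal(ordered[np.ix_(inv, inv)], m)

    def test_scrambled_blocks_restored(self):
        rng = np.random.default_rng(3)
        C, block = 12, 4
        truth = np.kron(np.eye(C // block), np.ones((block, block)))
        perm = rng.permutation(C)
        scrambled = truth[np.ix_(perm, perm)]
        labels = [f"r{i}" for i in range(C)]
        module_of = {labels[i]: f"m{perm[i] // block}" for i in range(C)}
        ordering = ModuleOrdering(labels, module_of)
        restored = order_by_module(scrambled, ordering)
        # block-mass statistic: fraction of mass inside diagonal blocks
        mask = np.kron(np.eye(C // block), np.ones((block, block)))
        assert (restored * mask).sum() / restored.sum() == pytest.approx(1.0)

    def test_modules_contiguous_after_ordering(self):
        labels = [f"r{i}" for i in range(6)]
        module_of = dict(zip(labels, ["b", "a", "b", "a", "b", "a"]))
        ordering = ModuleOrdering(labels, module_of)
        mods = [module_of[l] for l in ordering.ordered_labels]
        assert mods == sorted(mods, key=mods.index)


def test_composite_display_contract():
    rng = np.random.default_rng(0)
    z = rng.standard_normal((5, 5))
    z = (z + z.T) / 2
    sig = np.zeros((5, 5), dtype=bool)
    sig[0, 1] = sig[1, 0] = True
    comp = composite_matrix(z, sig)
    il = np.tril_indices(5, k=-1)
    assert np.array_equal(comp[il], z[il])          # lower: all values
    assert comp[0, 1] == z[0, 1]                    # upper: significant kept
    assert comp[0, 2] == 0.0 and comp[2, 4] == 0.0  # upper: rest masked
    assert np.all(np.diag(comp) == 0)
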