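import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from modeconn.datatypes import (
    MultivariateSignal,
    MVMDParams,
    ParameterError,
    ValidationError,
)
from modeconn.mvmd import (
    analytic_signal,
    instantaneous_attributes,
    mvmd_decompose,
    reconstruct,
)

from conftest import DT, T, make_tone


class TestAnalyticSignal:
    def test_zero_input_gives_zero_output(self):
        out = analytic_signal(np.zeros(64))
        assert np.all(out == 0)

    @given(st.integers(0, 2**31 - 1))
    def test_real_part_is_identity(self, seed):
        x = np.random.default_rng(seed).standard_normal(128)
        assert np.array_equal(analytic_signal(x).real, x)

    def test_cosine_quadrature_pair(self):
        """Hilbert transform of cos is sin, away from the record edges."""
        t = np.arange(1024) * DT
        x = np.cos(2 * np.pi * 0.1 * t)
        out = analytic_signal(x)
        interior = slice(51, 1024 - 51)  # skip first/last 5%
        err = np.abs(out.imag - np.sin(2 * np.pi * 0.1 * t))[interior]
        assert err.max() < 0.05

    def test_one_sided_spectrum(self):
        x = np.random.default_rng(0).standard_normal(256)
        spec = np.fft.fft(analytic_signal(x))
        neg = spec[129:]
        assert np.abs(neg).max() < 1e-9 * np.abs(spec).max()

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValidationError):
            analytic_signal(np.array([1.0, np.nan, 2.0]))


class TestDecompose:
    def test_two_tone_centers_match_fft_peaks(self, two_tone_signal,
                                              two_tone_modeset):
        # oracle: the two largest FFT power peaks of the input
        spec = np.abs(np.fft.rfft(two_tone_signal.data[0])) ** 2
        freqs = np.fft.rfftfreq(T, d=DT)
        peaks = np.sort(freqs[np.argsort(spec)[-2:]])
        assert np.all(
            np.abs(two_tone_modeset.omega - peaks) / peaks < 0.05
        )

    def test_single_tone_single_mode_recovers_input(self):
        x = make_tone(0.05)
        sig = MultivariateSignal(x[None, :], DT)
        ms = mvmd_decompose(sig, MVMDParams(K=1, alpha=1000))
        sl = slice(60, T - 60)
        err = np.linalg.norm(ms.modes[0, 0, sl] - x[sl])
        assert err / np.linalg.norm(x[sl]) < 1e-2

    def test_deterministic_repeat_is_bitwise_identical(self, two_tone_signal):
        p = MVMDParams(K=2, alpha=1000, seed=7, init="random")
        a = mvmd_decompose(two_tone_signal, p)
        b = mvmd_decompose(two_tone_signal, p)
        assert np.array_equal(a.omega, b.omega)
        assert np.array_equal(a.modes, b.modes)

    def test_too_many_modes_refused(self):
        sig = MultivariateSignal(np.random.default_rng(0).standard_normal((2, 40)), DT)
        with pytest.raises(ParameterError):
            mvmd_decompose(sig, MVMDParams(K=11, alpha=1000))

    @pytest.mark.parametrize("bad", [dict(K=0), dict(alpha=0.0),
                                     dict(alpha=-5.0), dict(tol=0.0)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParameterError):
            MVMDParams(**bad)

    def test_all_constant_signal_warns_and_returns_dc_modes(self):
        sig = MultivariateSignal(np.full((2, 64), 3.14), DT)
        with pytest.warns(UserWarning, match="all-constant"):
            ms = mvmd_decompose(sig, MVMDParams(K=2, alpha=1000, max_iter=50))
        assert np.all(ms.omega < 0.02)


class TestReconstruct:
    def test_zero_modes_give_zero_matrix(self, two_tone_modeset):
        import dataclasses
        ms = dataclasses.replace(two_tone_modeset,
                                 modes=np.zeros_like(two_tone_modeset.modes))
        assert np.all(reconstruct(ms) == 0)

    def test_noiseless_two_tone_reconstruction_error(self, two_tone_signal):
        # dual ascent enforces the reconstruction constraint on clean data
        ms = mvmd_decompose(two_tone_signal, MVMDParams(K=2, alpha=1000, tau=1.0))
        assert ms.converged
        err = np.linalg.norm(two_tone_signal.data - reconstruct(ms))
        assert err / np.linalg.norm(two_tone_signal.data) < 1e-2

    def test_modes_plus_residual_reproduce_input(self, two_tone_signal,
                                                 two_tone_modeset):
        total = reconstruct(two_tone_modeset) + two_tone_modeset.residual
        err = np.linalg.norm(total - two_tone_signal.data)
        assert err / np.linalg.norm(two_tone_signal.data) < 1e-12


class TestInstantaneousAttributes:
    def test_pure_tone_amplitude_and_frequency(self):
        mode = make_tone(0.05, amp=2.0)[None, :]
        amp, freq = instantaneous_attributes(mode, DT)
        sl = slice(100, T - 100)
        assert np.all(np.abs(amp[0, sl] - 2.0) / 2.0 < 0.02)
        assert np.all(np.abs(freq[0, sl] - 0.05) / 0.05 < 0.02)

    def test_zero_mode_convention(self):
        amp, freq = instantaneous_attributes(np.zeros((2, 64)), DT)
        assert np.all(amp == 0)
        assert np.all(freq == 0)

    def test_chirp_frequency_monotone_after_smoothing(self):
        t = np.arange(T) * DT
        # slowly increasing instantaneous frequency 30 -> 120 mHz
        phase = 2 * np.pi * (0.03 * t + 0.5 * (0.09 / t[-1]) * t ** 2)
        _, freq = instantaneous_attributes(np.cos(phase)[None, :], DT)
        sm = np.convolve(freq[0], np.ones(5) / 5, mode="valid")
        interior = sm[100:-100]
        assert np.all(np.diff(interior) > -1e-4)

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            instantaneous_attributes(np.zeros((1, 3)), DT)


class TestSolverProperties:
    def test_omega_sorted_and_in_range(self, two_tone_modeset,
                                       default_cohort_decomposed):
        _, _, mode_sets = default_cohort_decomposed
        for ms in [two_tone_modeset, *mode_sets]:
            assert np.all(np.diff(ms.omega) >= 0)
            assert ms.omega[0] >= 0
            assert ms.omega[-1] <= 0.5 / ms.dt + 1e-12

    def test_energy_near_orthogonality(self, two_tone_signal, two_tone_modeset):
        mode_energy = np.sum(two_tone_modeset.modes ** 2)
        assert mode_energy <= np.sum(two_tone_signal.data ** 2) * 1.05

    def test_bandwidth_does_not_grow_with_alpha(self):
        # bin-centered tones avoid sinc-leakage tails that would otherwise
        # dominate the second-moment bandwidth and mask the alpha effect
        from modeconn.bands import mode_bandwidth
        t = np.arange(T)
        x = (np.cos(2 * np.pi * 17 / T * t) + np.cos(2 * np.pi * 86 / T * t))
        sig = MultivariateSignal(np.tile(x, (3, 1)), DT)
        lo = mvmd_decompose(sig, MVMDParams(K=2, alpha=1000))
        hi = mvmd_decompose(sig, MVMDParams(K=2, alpha=10_000))
        for k in range(2):
            assert mode_bandwidth(hi, k) <= mode_bandwidth(lo, k) + 1e-12

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        data = np.stack([
            make_tone(0.03, phase=p) + 0.5 * make_tone(0.12, phase=2 * p)
            for p in rng.uniform(0, 2 * np.pi, 4)
        ])
        perm = np.array([2, 0, 3, 1])
        p = MVMDParams(K=2, alpha=1000)
        a = mvmd_decompose(MultivariateSignal(data, DT), p)
        b = mvmd_decompose(MultivariateSignal(data[perm], DT), p)
        assert np.allclose(a.omega, b.omega, atol=1e-10)
        assert np.allclose(a.modes[:, perm, :], b.modes, atol=1e-10)
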