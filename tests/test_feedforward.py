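"""Layer-by-layer behavior of the feed-forward pathway."""

import numpy as np
import pytest

from fstmd import ImageSequence, ModelConfig
from fstmd.feedforward import (
    build_kernels,
    feedforward_pass,
    lamina,
    lateral_inhibition,
    lobula,
    medulla_off,
    medulla_on,
    retina,
)
from fstmd.kernels import bandpass_kernel, gamma_kernel
from fstmd.synthetic import uniform_scene


def make_seq(frames, fs=1000.0):
    return ImageSequence(frames=np.asarray(frames, dtype=float), fs=fs)


class TestImageSequence:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            make_seq(np.full((3, 8, 8), 2.0))

    def test_rejects_bad_shape_and_fs(self):
        with pytest.raises(ValueError):
            make_seq(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            ImageSequence(frames=np.zeros((3, 4, 4)), fs=0.0)


class TestRetina:
    def test_constant_sequence_is_preserved(self):
        seq = make_seq(np.full((4, 16, 16), 0.5))
        P = retina(seq, sigma1=1.0)
        assert np.allclose(P, 0.5, atol=1e-12)

    def test_luminance_scale_is_proportional(self):
        seq = make_seq(np.full((4, 16, 16), 0.5))
        P = retina(seq, sigma1=1.0, luminance_scale=32.0)
        assert np.allclose(P, 16.0, atol=1e-10)

    def test_smoothing_reduces_spatial_variance(self, rng):
        seq = make_seq(rng.random((3, 40, 40)))
        P = retina(seq, sigma1=1.0)
        assert P[0].var() < seq.frames[0].var()

    def test_impulse_yields_gaussian_blob(self):
        frames = np.zeros((1, 21, 21))
        frames[0, 10, 10] = 1.0
        P = retina(make_seq(frames), sigma1=1.0)
        assert np.argmax(P[0]) == 10 * 21 + 10
        assert P[0, 10, 10] < 1.0  # spread out, not preserved


class TestLamina:
    def test_constant_input_gives_zero_after_warm_up(self):
        H = bandpass_kernel(2, 3, 6, 9)
        vol = np.full((300, 6, 6), 0.4)
        L = lamina(vol, H)
        assert np.abs(L[len(H):]).max() < 1e-9

    def test_step_response_is_biphasic_and_matches_cumsum(self):
        H = bandpass_kernel(2, 3, 6, 9)
        sig = np.zeros(250)
        sig[50:] = 1.0
        L = lamina(sig, H)
        # oracle: step response = cumulative sum of taps
        expected = np.concatenate([np.zeros(50), np.cumsum(H.taps)])[:250]
        expected[50 + len(H):] = np.cumsum(H.taps)[-1]
        assert np.allclose(L[:50 + len(H)], expected[:50 + len(H)], atol=1e-9)
        assert L[50:].max() > 1e-3        # positive lobe on the increase
        assert abs(L[-1]) < 1e-9          # settles back to zero

    def test_linearity(self, rng):
        H = bandpass_kernel(2, 3, 6, 9)
        vol = rng.random((60, 5, 5))
        assert np.allclose(lamina(2 * vol, H), 2 * lamina(vol, H), atol=1e-10)


class TestMedulla:
    def test_on_off_definitions(self):
        L = np.array([-1.0, 2.0, -3.0])
        assert np.array_equal(medulla_on(L), [0.0, 2.0, 0.0])
        assert np.all(medulla_on(-np.abs(L)) == 0.0)
        assert np.array_equal(medulla_on(medulla_on(L)), medulla_on(L))

    def test_off_channel_zero_for_nonnegative_input(self):
        g3 = gamma_kernel(5, 25)
        L = np.abs(np.random.default_rng(0).standard_normal((50, 3, 3)))
        assert np.all(medulla_off(L, g3) == 0.0)

    def test_off_impulse_is_delayed_gamma(self):
        g3 = gamma_kernel(5, 25)
        L = np.zeros((200, 3, 3))
        L[40, 1, 1] = -1.0
        S = medulla_off(L, g3)
        trace = S[:, 1, 1]
        assert np.allclose(trace[40 : 40 + len(g3)], g3.taps, atol=1e-12)
        assert np.argmax(trace) == 40 + 25  # peak lags the impulse by tau3
        assert np.all(S >= 0)

    def test_positive_homogeneity(self, rng):
        g3 = gamma_kernel(5, 25)
        L = rng.standard_normal((60, 4, 4))
        assert np.allclose(
            medulla_off(3.0 * L, g3), 3.0 * medulla_off(L, g3), atol=1e-10
        )


class TestLobula:
    def test_product_definition(self):
        assert lobula(np.array([2.0]), np.array([3.0]))[0] == 6.0
        assert np.all(lobula(np.zeros(5), np.ones(5)) == 0.0)
        with pytest.raises(ValueError, match="shape mismatch"):
            lobula(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_dark_target_coincidence_peak(self):
        """A dark square crossing a pixel at the matched speed produces a
        single dominant response near its departure from the pixel."""
        # 5 px target at 200 px/s, 1 kHz: pixel occluded for 25 samples,
        # matching the OFF delay tau3 = 25
        bundle = uniform_scene(
            200.0, fs=1000.0, width=80, min_x_reach=40, tail_frames=150,
            background_luminance=0.8,
        )
        out = feedforward_pass(bundle.seq)
        y, x = 12, 40
        trace = out.D[:, y, x]
        t_peak = int(np.argmax(trace))
        # departure of the trailing edge from pixel x
        t_depart = int((x + 2 - 10) / 0.2)
        assert abs(t_peak - t_depart) < 15
        # single dominant peak: everything 30+ samples away is far smaller
        mask = np.abs(np.arange(len(trace)) - t_peak) > 30
        assert trace[mask].max() < 0.3 * trace[t_peak]


class TestLateralInhibition:
    def test_zero_in_zero_out(self, default_config):
        bank = build_kernels(default_config, 1000.0)
        assert np.all(lateral_inhibition(np.zeros((3, 30, 30)), bank.W) == 0.0)

    def test_isolated_peak_survives(self, default_config):
        bank = build_kernels(default_config, 1000.0)
        D = np.zeros((1, 30, 30))
        D[0, 15, 15] = 1.0
        Dw = lateral_inhibition(D, bank.W)
        assert Dw[0, 15, 15] > 0
        assert np.argmax(Dw[0]) == 15 * 30 + 15

    def test_extended_ridge_suppressed_vs_compact_blob(self, default_config):
        bank = build_kernels(default_config, 1000.0)
        blob = np.zeros((1, 40, 40))
        blob[0, 18:23, 18:23] = 1.0
        ridge = np.zeros((1, 40, 40))
        ridge[0, 5:35, 18:23] = 1.0
        assert (
            lateral_inhibition(blob, bank.W).max()
            > lateral_inhibition(ridge, bank.W).max()
        )


class TestFeedforwardPass:
    def test_zero_feedback_equals_no_feedback(self, rng):
        seq = make_seq(rng.random((40, 32, 32)))
        base = feedforward_pass(seq)
        fed = feedforward_pass(seq, feedback_signal=np.zeros(seq.shape))
        assert np.array_equal(base.D_w, fed.D_w)

    def test_feedback_shape_mismatch_errors(self, rng):
        seq = make_seq(rng.random((10, 32, 32)))
        with pytest.raises(ValueError, match="does not match"):
            feedforward_pass(seq, feedback_signal=np.zeros((10, 16, 16)))

    def test_constant_sequence_silent(self):
        seq = make_seq(np.full((300, 32, 32), 0.6))
        out = feedforward_pass(seq)
        assert out.D.max() < 1e-12
        assert out.D_w.max() < 1e-12

    def test_nonnegativity_on_random_input(self, rng):
        seq = make_seq(rng.random((50, 32, 32)))
        out = feedforward_pass(seq)
        for vol in (out.S_ON, out.S_OFF, out.D, out.D_w):
            assert vol.min() >= 0.0

    def test_spatial_shift_equivariance_interior(self, rng):
        frames = np.zeros((60, 48, 64))
        patch = rng.random((60, 10, 10))
        a = frames.copy()
        a[:, 19:29, 20:30] = patch
        b = frames.copy()
        b[:, 19:29, 32:42] = patch  # shifted 12 px right
        out_a = feedforward_pass(make_seq(a))
        out_b = feedforward_pass(make_seq(b))
        # compare interior windows around each patch
        wa = out_a.D_w[:, 14:34, 15:35]
        wb = out_b.D_w[:, 14:34, 27:47]
        assert np.allclose(wa, wb, atol=1e-9)
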