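"""Vertex signal extraction, heart-rate estimation, and Fourier phase."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vesselflow as vf
from vesselflow.signals import assign_pixels_to_vertices


def _polyline(vertices):
    return vf.CenterlinePolyline(np.asarray(vertices, int),
                                 downsample_factor=1,
                                 source_path_length=len(vertices))


def _vss(signals, fps):
    signals = np.asarray(signals, float)
    V = signals.shape[0]
    return vf.VertexSignalSet(
        signals=signals,
        vertex_pixel_counts=np.ones(V, dtype=int),
        vertex_coords=np.column_stack([np.zeros(V, int), np.arange(V)]),
        fps=fps,
    )


class TestExtractVertexSignals:
    def test_uniform_frames_give_constant_signals(self):
        clip = vf.VideoClip(np.full((5, 10, 20, 3), 0.7), fps=30)
        mask = vf.VesselMask(np.ones((10, 20), dtype=bool))
        vss = vf.extract_vertex_signals(clip, mask, _polyline([(5, 3), (5, 16)]))
        np.testing.assert_allclose(vss.signals, 0.7, atol=1e-12)
        assert vss.vertex_pixel_counts.sum() == 200

    def test_two_blob_partition(self):
        """Two separated blobs, one vertex each: vertex signals equal the
        blob means exactly."""
        frames = np.full((4, 12, 30, 3), 0.5)
        m = np.zeros((12, 30), dtype=bool)
        m[4:7, 2:5] = True    # blob A around (5, 3)
        m[4:7, 24:27] = True  # blob B around (5, 25)
        frames[:, 4:7, 2:5, 1] = 0.2
        frames[:, 4:7, 24:27, 1] = 0.9
        clip = vf.VideoClip(frames, fps=30)
        vss = vf.extract_vertex_signals(clip, vf.VesselMask(m),
                                        _polyline([(5, 3), (5, 25)]))
        np.testing.assert_allclose(vss.signals[0], 0.2, atol=1e-12)
        np.testing.assert_allclose(vss.signals[1], 0.9, atol=1e-12)
        assert vss.vertex_pixel_counts.tolist() == [9, 9]

    def test_partition_matches_brute_force_nearest_vertex(self):
        """The implementation's pixel partition equals an explicit per-pixel
        nearest-vertex scan (ties to the lower vertex index)."""
        rng = np.random.default_rng(11)
        m = rng.uniform(size=(25, 40)) < 0.4
        m[12, 20] = True  # ensure non-empty
        mask = vf.VesselMask(m)
        verts = [(3, 4), (8, 15), (12, 20), (17, 28), (22, 36)]
        rows, cols, assign = assign_pixels_to_vertices(mask, _polyline(verts))
        va = np.asarray(verts, float)
        for r, c, a in zip(rows, cols, assign):
            d2 = (r - va[:, 0]) ** 2 + (c - va[:, 1]) ** 2
            best = np.flatnonzero(d2 == d2.min())[0]
            assert a == best
        assert len(rows) == mask.n_foreground


class TestEstimateHeartRate:
    def test_pure_sinusoid_lands_on_exact_bin(self):
        t = np.arange(300) / 30.0
        sig = 0.5 + 0.01 * np.sin(2 * np.pi * 1.2 * t)
        f, b = vf.estimate_heart_rate(_vss([sig, sig], 30.0))
        assert b == 12
        assert f == pytest.approx(1.2, abs=1e-12)

    def test_pump_waveform_fundamental_dominates(self):
        """The 1 s pump cycle sampled at 60 fps for 10 s yields a 1.0 Hz
        estimate; dominance of the fundamental is confirmed by an explicit
        O(N^2) DFT magnitude scan, independent of the FFT code path."""
        pump = vf.PumpParams(period=1.0, on_fraction=1 / 3, smoothing_sigma=0.0)
        t = np.arange(600) / 60.0
        sig = 0.5 - 0.05 * vf.pump_waveform(t, pump)
        f, b = vf.estimate_heart_rate(_vss([sig], 60.0), band=(0.8, 3.0))
        assert f == pytest.approx(1.0)

        n = len(sig)
        mags = {}
        for k in range(9, 31):  # bins covering 0.9..3.0 Hz
            w = np.exp(-2j * np.pi * k * np.arange(n) / n)
            mags[k] = abs(np.sum(sig * w))
        assert max(mags, key=mags.get) == 10  # 1.0 Hz at resolution 0.1 Hz
        assert b == 10

    def test_heart_rate_invariant_to_amplitude_and_offset(self):
        pump = vf.PumpParams()
        t = np.arange(480) / 60.0
        base = vf.pump_waveform(t, pump)
        for a, c in [(0.01, 0.2), (0.08, 0.6), (0.002, 0.9)]:
            f, _ = vf.estimate_heart_rate(_vss([c - a * base], 60.0))
            assert f == pytest.approx(1.0)

    def test_constant_signal_raises(self):
        with pytest.raises(ValueError, match="in-band"):
            vf.estimate_heart_rate(_vss([np.full(300, 0.5)], 30.0))

    def test_too_short_clip_raises(self):
        with pytest.raises(ValueError, match="short"):
            vf.estimate_heart_rate(_vss([np.zeros(30)], 30.0))


class TestVertexPhase:
    def test_cosine_reference_phase_is_zero(self):
        t = np.arange(300) / 30.0
        sig = np.cos(2 * np.pi * 1.0 * t)
        prof = vf.vertex_phase(_vss([sig, sig], 30.0), heart_bin=10, stride=1)
        np.testing.assert_allclose(prof.theta, 0.0, atol=1e-9)

    def test_delay_decreases_phase_by_two_pi_f_dt(self):
        """cos(2 pi f (t - dt)) with f = 1 Hz, dt = 0.25 s has phase -pi/2:
        the sign convention that makes phase drop downstream."""
        t = np.arange(300) / 30.0
        ref = np.cos(2 * np.pi * 1.0 * t)
        delayed = np.cos(2 * np.pi * 1.0 * (t - 0.25))
        prof = vf.vertex_phase(_vss([ref, delayed], 30.0), heart_bin=10, stride=1)
        assert prof.theta[0] == pytest.approx(0.0, abs=1e-6)
        assert prof.theta[1] == pytest.approx(-np.pi / 2, abs=1e-6)

    def test_identical_signals_have_zero_phase_difference(self):
        t = np.arange(240) / 30.0
        sig = 0.5 + 0.01 * np.sin(2 * np.pi * 1.0 * t)
        prof = vf.vertex_phase(_vss([sig, sig, sig], 30.0), heart_bin=8, stride=1)
        assert np.ptp(prof.theta) == pytest.approx(0.0, abs=1e-12)

    def test_stride_two_samples_every_second_vertex(self):
        t = np.arange(240) / 30.0
        sig = 0.5 + 0.01 * np.sin(2 * np.pi * 1.0 * t)
        prof = vf.vertex_phase(_vss([sig] * 7, 30.0), heart_bin=8, stride=2)
        assert prof.sampled_vertex_indices.tolist() == [0, 2, 4, 6]

    def test_frame_delayed_propagation_matches_phase_delay_relation(self):
        """With per-vertex delays that are exact multiples of the frame
        interval, pairwise phase differences equal -2 pi f dt (mod 2 pi)
        within 1e-3 rad."""
        fps, T, f = 30.0, 300, 1.0
        k = int(f * T / fps)
        t = np.arange(T) / fps
        base = 0.5 + 0.02 * np.cos(2 * np.pi * f * t)
        delays = [0, 2, 4, 6]  # frames
        sigs = [np.roll(base, d) for d in delays]  # roll = periodic delay
        prof = vf.vertex_phase(_vss(sigs, fps), heart_bin=k, stride=1)
        for i in range(len(delays) - 1):
            dt = (delays[i + 1] - delays[i]) / fps
            expected = -2 * np.pi * f * dt
            got = prof.theta[i + 1] - prof.theta[i]
            err = np.angle(np.exp(1j * (got - expected)))
            assert abs(err) < 1e-3

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0), st.floats(-0.4, 0.4))
    def test_phase_invariant_to_positive_scale_and_offset(self, scale, offset):
        t = np.arange(300) / 30.0
        sig = 0.5 + 0.05 * np.cos(2 * np.pi * 1.2 * t - 0.7)
        p1 = vf.vertex_phase(_vss([sig], 30.0), heart_bin=12, stride=1)
        p2 = vf.vertex_phase(_vss([offset + scale * sig], 30.0),
                             heart_bin=12, stride=1)
        assert p2.theta[0] == pytest.approx(p1.theta[0], abs=1e-9)
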