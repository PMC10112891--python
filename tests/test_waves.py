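"""Wave classification: gradient maps, order parameters, critical points,
episode rules, speeds, averaging, and statistics."""

import numpy as np
import pytest

from betawaves.preprocess import PhaseMovie
from betawaves.synth import PatternSpec, make_pattern_movie
from betawaves.waves import (LABELS, _CODE, align_and_average, classify_frames,
                             directionality_and_sigma_g, extract_episodes,
                             find_critical_points, gradient_coherence,
                             phase_gradient_map, shuffle_control, sigma_p,
                             stimulation_comparison, transition_statistics,
                             wave_speed, welch_from_stats)


def _movie_from_phase(phase, fr=1000.0):
    return PhaseMovie(amplitude=np.ones_like(phase), phase=phase,
                      frame_rate_hz=fr, edge_ms=0.0)


class TestPhaseGradient:
    def test_uniform_phase_zero_gradient(self):
        g = phase_gradient_map(np.full((8, 8), 0.7))
        np.testing.assert_allclose(g, 0.0)

    def test_plane_wave_exact_interior(self):
        xs = np.arange(10)
        phase = 0.3 * xs[:, None] * np.ones((1, 10))
        g = phase_gradient_map(phase)
        np.testing.assert_allclose(g[2:-2, :].real, 0.3, atol=1e-12)
        np.testing.assert_allclose(g[2:-2, :].imag, 0.0, atol=1e-12)

    def test_wrap_invariance(self):
        xs, ys = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        raw = 0.8 * xs + 100.0  # large offset forces wrapping
        wrapped = (raw + np.pi) % (2 * np.pi) - np.pi
        g_raw = phase_gradient_map(raw)
        g_wrap = phase_gradient_map(wrapped)
        np.testing.assert_allclose(g_raw, g_wrap, atol=1e-12)

    def test_missing_electrodes_excluded(self):
        phase = 0.3 * np.arange(10)[:, None] * np.ones((1, 10))
        valid = np.ones((10, 10), bool)
        valid[5, 5] = False
        g = phase_gradient_map(phase, valid)
        assert np.isnan(g[5, 5])
        np.testing.assert_allclose(g[3, 3].real, 0.3, atol=1e-12)


class TestSigmaG:
    def test_aligned_gradients_give_one(self):
        delta = np.full((10, 10), 1.0 + 0j)
        _, sg = directionality_and_sigma_g(delta)
        assert sg == pytest.approx(1.0)

    def test_uniform_directions_give_zero(self):
        rng = np.random.default_rng(0)
        ang = rng.uniform(-np.pi, np.pi, size=(200, 200))
        _, sg = directionality_and_sigma_g(np.exp(1j * ang))
        assert sg < 0.02

    def test_half_x_half_y(self):
        g = np.ones((10, 10), complex)
        g[5:] = 1j
        _, sg = directionality_and_sigma_g(g)
        assert sg == pytest.approx(1 / np.sqrt(2), rel=1e-12)

    def test_all_zero_gradient_undefined(self):
        _, sg = directionality_and_sigma_g(np.zeros((5, 5), complex))
        assert np.isnan(sg)


class TestGradientCoherence:
    def test_uniform_field_unchanged(self):
        delta = np.full((10, 10), np.exp(0.3j))
        lam = gradient_coherence(delta)
        np.testing.assert_allclose(lam, delta, atol=1e-12)

    def test_radial_field_vanishes_at_center(self):
        xs, ys = np.meshgrid(np.arange(11) - 5.0, np.arange(11) - 5.0,
                             indexing="ij")
        r = np.hypot(xs, ys)
        delta = np.where(r > 0, (xs + 1j * ys) / np.where(r > 0, r, 1), np.nan)
        lam = gradient_coherence(delta)
        assert np.abs(lam[5, 5]) < 0.05
        assert np.abs(lam[0, 5]) > np.abs(lam[3, 5]) > np.abs(lam[5, 5])

    def test_checkerboard_low_coherence(self):
        xs, ys = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        delta = np.where((xs + ys) % 2 == 0, 1.0 + 0j, -1.0 + 0j)
        lam = gradient_coherence(delta)
        assert np.abs(lam[2:-2, 2:-2]).max() < 0.2


class TestCriticalPoints:
    def test_plane_wave_has_none(self):
        lam = np.full((10, 10), 1.0 + 0.2j)
        assert find_critical_points(lam) == []

    def test_single_source_at_center(self):
        xs, ys = np.meshgrid(np.arange(10) - 4.5, np.arange(10) - 4.5,
                             indexing="ij")
        r = np.hypot(xs, ys)
        lam = (xs + 1j * ys) / r
        pts = find_critical_points(lam)
        assert len(pts) == 1
        (pos, kind) = pts[0]
        assert kind == "source"
        assert abs(pos[0] - 4.5) <= 1.0 and abs(pos[1] - 4.5) <= 1.0

    def test_two_sources_detected(self):
        # two radial fields stitched side by side (sum of two sources would
        # partially cancel between them)
        xs, ys = np.meshgrid(np.arange(16, dtype=float),
                             np.arange(8, dtype=float), indexing="ij")

        def radial(cx, cy):
            dx, dy = xs - cx, ys - cy
            r = np.maximum(np.hypot(dx, dy), 1e-9)
            return (dx + 1j * dy) / r

        lam = np.where(xs < 8, radial(3.5, 3.5), radial(11.5, 3.5))
        pts = find_critical_points(lam)
        # both sources found (plus the topologically required saddle between
        # them); in any case the frame has more than one critical point and
        # cannot be classified as radial
        sources = [p for p, kind in pts if kind == "source"]
        assert len(sources) == 2
        assert len(pts) != 1


class TestSigmaP:
    def test_synchronized_is_one(self):
        assert sigma_p(np.full((10, 10), 1.2)) == pytest.approx(1.0)

    def test_uniform_phases_near_zero(self):
        rng = np.random.default_rng(1)
        assert sigma_p(rng.uniform(-np.pi, np.pi, (300, 300))) < 0.01

    def test_two_groups_quarter_turn_apart(self):
        ph = np.zeros((10, 10))
        ph[5:] = np.pi / 2
        assert sigma_p(ph) == pytest.approx(1 / np.sqrt(2), rel=1e-12)


class TestClassifyFrames:
    def test_pattern_types_recovered(self):
        spec = PatternSpec(segments=[
            dict(kind="planar", duration_ms=50, wavevector=(0.5, 0.2),
                 phase_noise_sd=0.2),
            dict(kind="synchronized", duration_ms=50),
            dict(kind="random", duration_ms=50),
        ], seed=2)
        movie, labels, _ = make_pattern_movie(spec)
        cls = classify_frames(movie)
        assert (cls.labels[:50] == _CODE["planar"]).mean() > 0.9
        assert (cls.labels[50:100] == _CODE["synchronized"]).all()
        assert (cls.labels[100:] == _CODE["random"]).mean() > 0.7

    def test_random_phases_classified_random(self):
        # Monte-Carlo over i.i.d. uniform phase frames.  With the raw
        # per-electrode gradient estimator essentially all frames are random
        # (the residue is 'radial' frames whose coherence map shows a single
        # critical point by chance).  The default smoothed-gradient sigma_g
        # admits a few percent of chance planar frames on a 10x10 grid --
        # harmless for episodes, which need six in a row.
        rng = np.random.default_rng(3)
        ph = rng.uniform(-np.pi, np.pi, size=(10, 10, 1000))
        cls_raw = classify_frames(_movie_from_phase(ph), gradient_smoothing=0)
        frac = {k: (cls_raw.labels == c).mean() for k, c in _CODE.items()}
        assert frac["random"] > 0.95
        assert frac["planar"] < 0.01
        assert frac["synchronized"] < 0.01
        cls = classify_frames(_movie_from_phase(ph))
        frac = {k: (cls.labels == c).mean() for k, c in _CODE.items()}
        assert frac["random"] > 0.9
        assert frac["synchronized"] < 0.01

    def test_threshold_monotonicity(self):
        spec = PatternSpec(segments=[
            dict(kind="planar", duration_ms=100, phase_noise_sd=0.8),
            dict(kind="synchronized", duration_ms=100, phase_noise_sd=0.4),
        ], seed=4)
        movie, _, _ = make_pattern_movie(spec)
        # raising one threshold at a time never increases that class's count
        n_planar = [
            (classify_frames(movie, sigma_g_threshold=th).labels
             == _CODE["planar"]).sum() for th in (0.4, 0.6, 0.8)]
        assert n_planar[0] >= n_planar[1] >= n_planar[2]
        n_sync = [
            (classify_frames(movie, sigma_p_threshold=th).labels
             == _CODE["synchronized"]).sum() for th in (0.7, 0.85, 0.95)]
        assert n_sync[0] >= n_sync[1] >= n_sync[2]

    def test_rotation_equivariance(self):
        spec = PatternSpec(segments=[
            dict(kind="planar", duration_ms=80, wavevector=(0.4, 0.1),
                 phase_noise_sd=0.1),
            dict(kind="radial", duration_ms=80, kappa=0.6,
                 phase_noise_sd=0.05),
        ], seed=5)
        movie, _, _ = make_pattern_movie(spec)
        rot = PhaseMovie(amplitude=np.rot90(movie.amplitude, axes=(0, 1)),
                         phase=np.rot90(movie.phase, axes=(0, 1)),
                         frame_rate_hz=movie.frame_rate_hz, edge_ms=0.0)
        c0 = classify_frames(movie)
        c1 = classify_frames(rot)
        np.testing.assert_array_equal(c0.labels, c1.labels)
        ev0 = extract_episodes(c0)
        ev1 = extract_episodes(c1)
        for a, b in zip(ev0, ev1):
            if np.isfinite(a.speed_cm_s):
                assert b.speed_cm_s == pytest.approx(a.speed_cm_s, rel=1e-6)
                rotated = (a.direction_rad + np.pi / 2 + np.pi) \
                    % (2 * np.pi) - np.pi
                assert np.angle(np.exp(1j * (b.direction_rad - rotated))) \
                    == pytest.approx(0.0, abs=1e-6)


class TestEpisodes:
    def _labels_to_events(self, runs):
        nt = sum(n for _, n in runs)
        phase = np.zeros((10, 10, nt))
        movie = _movie_from_phase(phase)
        cls = classify_frames(movie)
        cls.labels[:] = np.concatenate(
            [np.full(n, _CODE[k], dtype=np.int64) for k, n in runs])
        return extract_episodes(cls)

    def test_five_frames_become_random(self):
        ev = self._labels_to_events([("planar", 5), ("random", 20)])
        assert all(e.kind == "random" for e in ev)

    def test_six_frames_register(self):
        ev = self._labels_to_events([("planar", 6), ("random", 20)])
        assert ev[0].kind == "planar"
        assert ev[0].duration_ms == 6.0

    def test_sequence_with_annotations(self):
        ev = self._labels_to_events(
            [("planar", 7), ("synchronized", 10), ("planar", 6)])
        kinds = [e.kind for e in ev]
        assert kinds == ["planar", "synchronized", "planar"]
        assert [e.duration_ms for e in ev] == [7.0, 10.0, 6.0]
        assert ev[2].preceding == "synchronized"
        assert ev[1].preceding == "planar" and ev[1].following == "planar"


class TestWaveSpeed:
    def test_hand_computed_value(self):
        # f = 20 Hz, |grad| = 0.5 rad per 400 um electrode -> 10.05 cm/s
        xs = np.arange(10)
        nt = 100
        phase = (2 * np.pi * 20.0 * np.arange(nt) / 1000.0)[None, None, :] \
            - (0.5 * xs)[:, None, None] * np.ones((1, 10, 1))
        phase = (phase + np.pi) % (2 * np.pi) - np.pi
        v, f, g = wave_speed(phase, 1000.0)
        assert f == pytest.approx(20.0, rel=1e-6)
        assert g == pytest.approx(0.5, rel=1e-6)
        assert v == pytest.approx(2 * np.pi * 20.0 / 0.5 * 0.04, rel=1e-6)

    @pytest.mark.parametrize("scale", [2.0, 0.5])
    def test_linearity_in_frequency_and_gradient(self, scale):
        def build(f_hz, k):
            xs = np.arange(10)
            ph = (2 * np.pi * f_hz * np.arange(200) / 1000.0)[None, None, :] \
                - (k * xs)[:, None, None] * np.ones((1, 10, 1))
            return (ph + np.pi) % (2 * np.pi) - np.pi
        v0, _, _ = wave_speed(build(20.0, 0.5), 1000.0)
        v_f, _, _ = wave_speed(build(20.0 * scale, 0.5), 1000.0)
        v_k, _, _ = wave_speed(build(20.0, 0.5 * scale), 1000.0)
        assert v_f == pytest.approx(scale * v0, rel=1e-6)
        assert v_k == pytest.approx(v0 / scale, rel=1e-6)

    def test_speed_recovery_across_range(self):
        # noiseless plane waves spanning 5-60 cm/s recovered within 2%
        for v_true in (5.0, 15.0, 30.0, 60.0):
            k = 2 * np.pi * 20.0 * 0.04 / v_true
            spec = PatternSpec(segments=[dict(
                kind="planar", duration_ms=200, freq_hz=20.0,
                wavevector=(k, 0.0))])
            movie, _, truth = make_pattern_movie(spec)
            v, _, _ = wave_speed(movie.phase, 1000.0)
            assert v == pytest.approx(v_true, rel=0.02)
            assert truth.speed_cm_s[0] == pytest.approx(v_true, rel=1e-9)


class TestAlignAndAverage:
    def _planar_movie(self, n_events=4, direction=(0.5, 0.0)):
        segs = []
        for _ in range(n_events):
            segs.append(dict(kind="planar", duration_ms=60,
                             wavevector=direction))
            segs.append(dict(kind="synchronized", duration_ms=140))
        spec = PatternSpec(segments=segs, seed=6)
        movie, _, _ = make_pattern_movie(spec)
        cls = classify_frames(movie)
        return movie, extract_episodes(cls)

    def test_identical_events_average_to_single_event(self):
        movie, events = self._planar_movie()
        out = align_and_average(movie, events, mode="onset", rotate=False,
                                window_ms=40)
        assert out["n_events"] >= 2
        # averaged phase map keeps the plane-wave gradient (the generator
        # phase is -k.x, so the gradient is -k)
        g = phase_gradient_map(out["phase"][..., out["phase"].shape[-1] // 2])
        assert np.nanmean(g.real) == pytest.approx(-0.5, abs=0.05)

    def test_phase_alignment_zeroes_phase_at_origin(self):
        movie, events = self._planar_movie()
        out = align_and_average(movie, events, mode="phase", rotate=False,
                                window_ms=40)
        mid = out["phase"].shape[-1] // 2
        mean_phase = np.angle(np.exp(1j * out["phase"][..., mid]).mean())
        f_ref = out["f_ref_hz"]
        # within one frame of zero phase
        assert abs(mean_phase) < 2 * np.pi * f_ref / 1000.0 * 1.5

    def test_rotation_merges_orthogonal_waves(self):
        m_x, ev_x = self._planar_movie(direction=(0.5, 0.0))
        m_y, ev_y = self._planar_movie(direction=(0.0, 0.5))
        out_x = align_and_average(m_x, ev_x, mode="onset", rotate=True,
                                  window_ms=30)
        out_y = align_and_average(m_y, ev_y, mode="onset", rotate=True,
                                  window_ms=30)
        mid = out_x["phase"].shape[-1] // 2
        gx = phase_gradient_map(out_x["phase"][..., mid])
        gy = phase_gradient_map(out_y["phase"][..., mid])
        # after rotation both propagate identically (no cancellation)
        assert np.abs(np.nanmean(gx)) > 0.4
        ang = np.angle(np.nanmean(gx) / np.nanmean(gy))
        assert abs(ang) < 0.1


class TestTransitions:
    class _Ev:
        def __init__(self, kind, pre=None, post=None):
            self.kind, self.preceding, self.following = kind, pre, post

    def test_sync_flanked_planars(self):
        events = [self._Ev("synchronized")] * 10 + [self._Ev("random")] * 10
        events += [self._Ev("planar", "synchronized", "synchronized")] * 5
        out = transition_statistics(events)
        assert out["table"].loc["synchronized", "synchronized"] == 5
        assert out["table"].loc["synchronized", "random"] == 0
        assert out["p_null_sync"] == pytest.approx(0.5)

    def test_null_calibration_uniform_p(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            events = [self._Ev("synchronized")] * 50 + [self._Ev("random")] * 50
            for _k in range(30):
                events.append(self._Ev(
                    "planar", "synchronized",
                    "synchronized" if rng.random() < 0.5 else "random"))
            pvals.append(transition_statistics(events)["p_synchronized_to_sync"])
        pvals = np.array(pvals)
        # one-sided binomial p under the null is stochastically >= uniform
        assert (pvals < 0.05).mean() < 0.1
        assert pvals.mean() > 0.3

    def test_reference_volume_counts_are_overwhelming(self):
        # 421 sync-preceded planar waves, 364 ending synchronized, against a
        # marginal of 3906 synchronized vs 4293 random episodes
        events = [self._Ev("synchronized")] * 3906 + [self._Ev("random")] * 4293
        events += [self._Ev("planar", "synchronized", "synchronized")] * 364
        events += [self._Ev("planar", "synchronized", "random")] * 57
        out = transition_statistics(events)
        assert out["p_synchronized_to_sync"] < 1e-10


class TestShuffleControl:
    def test_identity_permutation_is_noop(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(5, 5, 100))
        out = shuffle_control(m, permutation=np.arange(25))
        np.testing.assert_array_equal(out, m)

    def test_synchronized_movie_stays_synchronized(self):
        spec = PatternSpec(segments=[dict(kind="synchronized",
                                          duration_ms=300)], seed=9)
        movie, _, _ = make_pattern_movie(spec)
        shuffled = shuffle_control(movie, seed=1)
        cls = classify_frames(shuffled)
        assert (cls.labels == _CODE["synchronized"]).all()

    def test_planar_waves_destroyed_by_shuffle(self):
        spec = PatternSpec(segments=[dict(kind="planar", duration_ms=300,
                                          wavevector=(0.5, 0.0))], seed=10)
        movie, _, _ = make_pattern_movie(spec)
        assert (classify_frames(movie).labels == _CODE["planar"]).all()
        shuffled = shuffle_control(movie, seed=2)
        cls = classify_frames(shuffled)
        assert (cls.labels == _CODE["planar"]).mean() < 0.05


class TestStimulationComparison:
    def test_identical_samples_p_half(self):
        out = stimulation_comparison([5, 5, 5], [5, 5, 5])
        assert out["p"] == 0.5

    def test_matches_hand_computed_welch(self):
        a, b = [6.0, 6.0, 7.0], [9.0, 9.0, 10.0]
        out = stimulation_comparison(a, b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / 3, np.var(b, ddof=1) / 3
        t_hand = (mb - ma) / np.sqrt(va + vb)
        assert out["t"] == pytest.approx(t_hand, rel=1e-12)
        assert 0 < out["p"] < 0.05

    def test_reference_summary_statistics_significant(self):
        # negative-stimulation comparison: 6.4+-2.3 vs 9+-2.6, n=10 each
        _, p_neg = welch_from_stats(6.4, 2.3, 10, 9.0, 2.6, 10)
        assert p_neg < 0.05
        # positive stimulation suppresses: 2.8+-1.9 vs baseline
        _, p_pos = welch_from_stats(2.8, 1.9, 10, 6.4, 2.3, 10)
        assert p_pos < 0.05
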