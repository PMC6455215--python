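import numpy as np
import pytest

from gss_hdemg.initpoints import (
    ActiveSegment,
    InitialPointEstimator,
    OpticsOrdering,
    align_segments,
    detect_active_segments,
    detection_threshold,
    extract_valleys,
    optics_order,
    representatives_to_initial_points,
    upsample,
)
from gss_hdemg.preprocess import bandpass, make_single_differential
from gss_hdemg.simulate import ElectrodeGrid, EMGRecording


def brute_force_optics(feats, min_pts):
    """Independent O(n^2) OPTICS with epsilon = infinity (oracle)."""
    n = len(feats)
    dist = np.linalg.norm(feats[:, None, :] - feats[None, :, :], axis=2)
    core = np.sort(dist, axis=1)[:, min_pts]
    reach = np.full(n, np.inf)
    done = np.zeros(n, bool)
    order, rd = [], []
    cur = 0
    for step in range(n):
        order.append(cur)
        rd.append(np.inf if step == 0 else reach[cur])
        done[cur] = True
        if step == n - 1:
            break
        for j in range(n):
            if not done[j]:
                reach[j] = min(reach[j], max(core[cur], dist[cur, j]))
        best, best_rd = -1, np.inf
        for j in range(n):
            if not done[j] and reach[j] < best_rd:
                best, best_rd = j, reach[j]
        if best < 0:
            best = int(np.flatnonzero(~done)[0])
        cur = best
    return np.array(order), np.array(rd)


class TestUpsample:
    def test_tone_preserved(self):
        fs = 4096.0
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * 100 * t)
        rec = _mono(x[None, :], fs)
        up = upsample(rec, 10000.0)
        assert up.fs_hz == 10000.0
        mid = slice(1000, -1000)
        assert abs(np.abs(up.data[0][mid]).max() - 1.0) < 0.01

    def test_constant_signal(self):
        rec = _mono(np.full((1, 2048), 3.3), 4096.0)
        up = upsample(rec, 10000.0)
        assert np.allclose(up.data, 3.3, atol=1e-6)

    def test_round_trip_error_small(self):
        """Band-limited noise survives upsample -> decimate within 1e-3 RMS."""
        from scipy import signal as sps

        rng = np.random.default_rng(0)
        fs = 4096.0
        x = rng.standard_normal(int(2 * fs))
        sos = sps.butter(6, 500, fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
        rec = _mono(x[None, :], fs)
        up = upsample(rec, 2 * fs)  # rational factor: exact decimation grid
        back = up.data[0][::2]
        err = np.linalg.norm(back - x) / np.linalg.norm(x)
        assert err < 1e-3

    def test_downsampling_rejected(self):
        with pytest.raises(ValueError):
            upsample(_mono(np.zeros((1, 100)), 4096.0), 2000.0)


class TestDetectionThreshold:
    def test_gaussian_with_spikes(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100_000)
        x[rng.choice(100_000, 50, replace=False)] = 20.0
        assert 3.0 <= detection_threshold(x, K=4.0) <= 6.0

    def test_scale_homogeneity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(20_000)
        assert detection_threshold(2.5 * x) == pytest.approx(
            2.5 * detection_threshold(x), rel=1e-9
        )

    def test_false_positive_rate_on_pure_noise(self):
        """At K=4 the threshold sits near 4 sigma: few noise crossings."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100_000)
        thr = detection_threshold(x)
        # Gaussian tail beyond ~3.9 sigma: expect a handful of samples
        assert np.sum(np.abs(x) > thr) < 30

    def test_zero_input_warns(self):
        with pytest.warns(UserWarning):
            assert detection_threshold(np.zeros(100)) == 0.0


class TestSegmentation:
    def test_isolated_and_paired_spikes(self):
        fs = 10000.0
        x = np.zeros(5000)
        x[1000] = 5.0
        x[3000] = 4.0
        x[3100] = 4.5  # 10 ms apart from 3000
        segs = detect_active_segments(x, thr=2.0, fs=fs)
        assert len(segs) == 3
        assert segs[0].peak_time == pytest.approx(0.1)

    def test_window_collision_keeps_larger_peak(self):
        fs = 10000.0
        x = np.zeros(2000)
        x[1000] = 3.0
        x[1005] = 5.0  # 0.5 ms apart: collision inside the 2-ms window
        segs = detect_active_segments(x, thr=2.0, fs=fs)
        assert len(segs) == 1
        assert segs[0].peak_time == pytest.approx(1005 / fs)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(8000)
        x[[2000, 4000, 6000]] = 12.0
        thr = detection_threshold(x)
        a = detect_active_segments(x, thr)
        b = detect_active_segments(np.roll(x, 37), thr)
        ta = np.array([s.peak_time for s in a])
        tb = np.array([s.peak_time for s in b])
        assert np.allclose(tb - ta, 37 / 10000.0, atol=1e-9)


class TestAlignment:
    def _segment(self, w, fs=10000.0):
        return ActiveSegment(channel=0, window=(0, w.size), peak_time=0.0, waveform=w, fs=fs)

    def test_fourier_shift_recovery(self):
        """A 0.23-sample shift is recovered within 0.05 samples."""
        from gss_hdemg.initpoints import _fourier_shift

        n = 20
        t = np.arange(n) - 10.0
        base = np.exp(-(t**2) / 4.0)
        shifted = _fourier_shift(base, 0.23)
        seg = align_segments([self._segment(shifted)])[0]
        est_shift = seg.peak_time * 10000.0 - 10.0
        assert abs(est_shift - 0.23) < 0.05

    def test_centered_waveform_untouched(self):
        t = np.arange(20) - 10.0
        w = np.exp(-(t**2) / 4.0)
        out = align_segments([self._segment(w)])[0]
        assert np.allclose(out.waveform, w, atol=1e-6)

    def test_idempotence(self):
        from gss_hdemg.initpoints import _fourier_shift

        t = np.arange(20) - 10.0
        w = _fourier_shift(np.exp(-(t**2) / 4.0), 0.4)
        once = align_segments([self._segment(w)])[0]
        twice = align_segments([once])[0]
        # once aligned, the residual shift found by a second pass is within
        # the sub-sample interpolation error (peak already at the center)
        residual = twice.peak_time * 10000.0 - 10.0
        assert abs(residual) < 0.05
        assert np.allclose(once.waveform, twice.waveform, atol=0.02)


class TestOptics:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        feats = np.vstack(
            [rng.normal(0, 1, (80, 6)), rng.normal(8, 1, (70, 6)), rng.normal(-7, 2, (50, 6))]
        )
        ordering = optics_order(feats, min_pts=10)
        o_order, o_rd = brute_force_optics(feats, 10)
        assert np.array_equal(ordering.order, o_order)
        assert np.allclose(ordering.reachability[1:], o_rd[1:], rtol=1e-12)
        assert np.isinf(ordering.reachability[0])

    def test_two_tight_groups_show_two_valleys(self):
        rng = np.random.default_rng(6)
        feats = np.vstack([rng.normal(0, 0.05, (50, 3)), rng.normal(5, 0.05, (50, 3))])
        ordering = optics_order(feats, min_pts=5)
        # one high-RD jump separates the two dense runs
        rd = ordering.reachability[1:]
        assert np.sum(rd > 1.0) == 1
        reps = extract_valleys(ordering, theta=0.75, min_width=5)
        assert len(reps) == 2

    def test_identical_points_zero_reachability(self):
        feats = np.zeros((30, 4))
        ordering = optics_order(feats, min_pts=5)
        assert np.all(ordering.reachability[1:] == 0.0)

    def test_too_few_points_warns_empty(self):
        with pytest.warns(UserWarning):
            ordering = optics_order(np.zeros((3, 2)), min_pts=10)
        assert ordering.order.size == 0


class TestValleys:
    def _ordering(self, rd, min_pts):
        n = len(rd)
        return OpticsOrdering(order=np.arange(n), reachability=np.array(rd), min_pts=min_pts)

    def test_stated_two_valley_profile(self):
        rd = [np.inf, 1, 1, 1, 9, 1, 1, 1]
        reps = extract_valleys(self._ordering(rd, 3))
        assert len(reps) == 2
        assert all(r.rd_at_rep == 1.0 for r in reps)

    def test_flat_profile_single_valley(self):
        reps = extract_valleys(self._ordering([np.inf] + [2.0] * 12, 4))
        assert len(reps) == 1

    def test_representative_is_minimum_rd(self):
        rd = [np.inf, 3, 1, 2, 9, 5, 4, 6]
        reps = extract_valleys(self._ordering(rd, 3))
        for rep in reps:
            a, b = rep.valley
            assert rep.rd_at_rep == min(rd[a:b])


class TestInitialPoints:
    def test_time_to_sample_and_dedup(self):
        segs = [
            ActiveSegment(0, (0, 20), 1.00000, np.zeros(20)),
            ActiveSegment(1, (0, 20), 1.0003, np.zeros(20)),  # 0.3 ms away: dropped
            ActiveSegment(2, (0, 20), 0.5, np.zeros(20)),
        ]
        from gss_hdemg.initpoints import ClusterRepresentative

        reps = [ClusterRepresentative(segment=s, valley=(0, 1), rd_at_rep=i) for i, s in enumerate(segs)]
        pts = representatives_to_initial_points(reps, fs_decomp=4096.0)
        assert len(pts) == 2
        assert {p.sample_index for p in pts} == {4096, 2048}

    def test_estimator_clusters_are_time_locked(self, clean_signal):
        """On a clean 30 dB / 10% signal, most clusters behind the initial
        points are time-locked to a single simulated MU (proxies matching
        one MU's firings within +-0.5 ms after constant-lag alignment)."""
        from gss_hdemg.validation import cluster_correct

        rec, truth = clean_signal
        sd = make_single_differential(bandpass(rec))
        ipe = InitialPointEstimator(max_points=30).fit(sd)
        assert len(ipe.initial_points_) >= 10
        correct = sum(
            cluster_correct(proxies, truth, quota=0.6)
            for proxies in ipe.cluster_proxy_times_
            if len(proxies)
        )
        assert correct / len(ipe.cluster_proxy_times_) >= 0.6


def _mono(data, fs):
    c = data.shape[0]
    return EMGRecording(
        data=data, fs_hz=fs, grid=ElectrodeGrid(rows=c, cols=1, ied_mm=5.0, fs_hz=fs)
    )
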