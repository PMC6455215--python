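import numpy as np
import pytest

from gss_hdemg.gss_core import (
    GCKCConfig,
    KalmanState,
    MUFilter,
    assign_alpha,
    ckc_estimate,
    decompose_mu,
    gckc_update,
    init_filter,
    kalman_step,
    optimize_threshold,
    pnr,
)
from gss_hdemg.initpoints import InitialPoint
from gss_hdemg.preprocess import ExtendedObservation, WhiteningModel


def _obs(X, fs=4096.0, whitened=True):
    wh = None
    if whitened:
        n = X.shape[0]
        wh = WhiteningModel(
            W=np.eye(n), U=np.eye(n), D=np.ones(n), mean_vector=np.zeros(n), regularization=0.0
        )
    return ExtendedObservation(
        X=X, R=1, fs_hz=fs, n_channels=X.shape[0], whitening=wh
    )


def _toy_mixture(n_sources=3, n_channels=24, duration_s=4.0, fs=2048.0, snr_db=20.0, seed=0):
    """Convolutive toy: distinct biphasic kernels, regular-ish trains."""
    rng = np.random.default_rng(seed)
    m = int(duration_s * fs)
    data = np.zeros((n_channels, m))
    trains = []
    for j in range(n_sources):
        rate = 9.0 + 2.0 * j
        t = rng.uniform(0, 1 / rate)
        times = []
        while t < duration_s - 0.05:
            times.append(t)
            t += max(0.02, rng.normal(1 / rate, 0.14 / rate))
        times = np.array(times)
        trains.append(times)
        kernel = rng.standard_normal((n_channels, 9)) * np.hanning(9)
        idx = np.round(times * fs).astype(int)
        train = np.zeros(m)
        train[idx] = 1.0
        for c in range(n_channels):
            data[c] += np.convolve(train, kernel[c], mode="same")
    noise = rng.standard_normal(data.shape)
    noise *= np.sqrt(np.mean(data**2) / np.mean(noise**2) / 10 ** (snr_db / 10))
    return data + noise, trains, fs


class TestCkcEstimator:
    def test_scalar_identity_case(self):
        """Single source, no extension: t = var(t)' Rxx^-1 X recovers t."""
        rng = np.random.default_rng(0)
        t = rng.standard_normal(5000)
        obs = _obs(t[None, :], whitened=False)
        r = np.array([np.mean(t * t)])
        est = ckc_estimate(obs, MUFilter(r=r))
        assert np.allclose(est, t, atol=1e-6)

    def test_zero_filter_zero_train(self):
        rng = np.random.default_rng(1)
        obs = _obs(rng.standard_normal((4, 100)))
        assert np.allclose(ckc_estimate(obs, np.zeros(4)), 0.0)

    def test_whitened_firing_column_recovers_source(self):
        """Initializing on a true firing separates that source's train."""
        from gss_hdemg.preprocess import extend, whiten
        from gss_hdemg.simulate import ElectrodeGrid, EMGRecording

        data, trains, fs = _toy_mixture(seed=2)
        rec = EMGRecording(
            data=data, fs_hz=fs,
            grid=ElectrodeGrid(rows=data.shape[0], cols=1, ied_mm=5.0, fs_hz=fs),
        )
        obs = whiten(extend(rec, R=8))
        times = trains[0]
        m0 = int(round(times[5] * fs))
        t_est = ckc_estimate(obs, obs.X[:, m0])
        order = np.argsort(t_est)[::-1]
        top = set(order[: len(times) * 2].tolist())
        hits = sum(
            any(abs(i - round(ft * fs)) <= 1 for i in top) for ft in times
        )
        assert hits / len(times) >= 0.95


class TestInitFilter:
    def test_column_extraction(self):
        rng = np.random.default_rng(3)
        obs = _obs(rng.standard_normal((6, 50)))
        p = InitialPoint(sample_index=17, source_channel=0, provenance=0)
        assert np.array_equal(init_filter(obs, p).r, obs.X[:, 17])

    def test_out_of_range_rejected(self):
        obs = _obs(np.zeros((2, 10)))
        with pytest.raises(ValueError):
            init_filter(obs, InitialPoint(sample_index=10, source_channel=0, provenance=0))


class TestPnr:
    def test_hand_computed_value(self):
        values = np.array([2.0] * 10 + [0.2] * 90)
        assert pnr(values, 1.0) == pytest.approx(20.0, abs=1e-9)

    def test_equal_energy_classes_zero_db(self):
        values = np.array([1.0] * 5 + [-1.0] * 5)
        assert pnr(values, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        v = np.abs(rng.standard_normal(1000)) + 0.01
        thr = 1.0
        assert pnr(3.7 * v, 3.7 * thr) == pytest.approx(pnr(v, thr), abs=1e-9)

    def test_empty_class_is_nan(self):
        assert np.isnan(pnr(np.ones(10), 5.0))


class TestOptimizeThreshold:
    def _bimodal(self, seed=5):
        rng = np.random.default_rng(seed)
        v = 0.15 * rng.standard_normal(8000)
        small = rng.choice(8000, 40, replace=False)
        big = rng.choice(np.setdiff1d(np.arange(8000), small), 40, replace=False)
        v[small] = 1.0 + 0.05 * rng.standard_normal(40)
        v[big] = 10.0 + 0.5 * rng.standard_normal(40)
        return v

    def test_threshold_lands_between_modes(self):
        v = self._bimodal()
        thr, (lo, hi), _ = optimize_threshold(v, np.random.default_rng(0))
        assert 1.2 < thr <= 10.0
        assert lo <= thr <= hi

    def test_argmax_contract(self):
        v = self._bimodal()
        thr, _, best = optimize_threshold(v, np.random.default_rng(0), n_boot=0)
        for other in np.linspace(0.2, 9.0, 25):
            assert best >= pnr(v, other) - 1e-9

    def test_scale_homogeneity(self):
        v = self._bimodal()
        thr1, _, p1 = optimize_threshold(v, np.random.default_rng(1), n_boot=0)
        thr2, _, p2 = optimize_threshold(4.2 * v, np.random.default_rng(1), n_boot=0)
        assert thr2 == pytest.approx(4.2 * thr1, rel=1e-9)
        assert p2 == pytest.approx(p1, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold(np.ones(100))

    def test_min_spikes_constraint(self):
        v = self._bimodal()
        thr, _, _ = optimize_threshold(v, np.random.default_rng(2), n_boot=0, min_spikes=60)
        # at least 60 peaks must stay above the constrained threshold
        assert np.sum(v > thr) >= 60


class TestAssignAlpha:
    def test_confident_spike_full_weight(self):
        fs = 4096.0
        v = np.zeros(4096)
        v[1000] = 5.0
        spikes, alphas = assign_alpha(v, 1.0, (0.5, 2.0), None, fs)
        assert spikes.tolist() == [1000]
        assert alphas.tolist() == [1.0]

    def test_marginal_spike_matching_template(self):
        """A marginal spike whose EMG segment equals the confident-spike
        template keeps alpha = 1."""
        fs = 4096.0
        rng = np.random.default_rng(6)
        v = np.zeros(4096)
        src = 0.01 * rng.standard_normal(4096)
        shape = np.sin(np.linspace(0, 2 * np.pi, 8))
        for p in (500, 1000, 1500, 2000):
            v[p] = 5.0
            src[p - 4 : p + 4] += shape
        v[3000] = 1.5  # marginal
        src[2996 : 3004] += shape
        spikes, alphas = assign_alpha(v, 2.0, (1.0, 3.0), src, fs, corr_threshold=0.8)
        i = list(spikes).index(3000)
        assert alphas[i] == 1.0

    def test_marginal_noise_attenuated(self):
        fs = 4096.0
        rng = np.random.default_rng(7)
        v = np.zeros(4096)
        src = 0.01 * rng.standard_normal(4096)
        shape = np.sin(np.linspace(0, 2 * np.pi, 8))
        for p in (500, 1000, 1500, 2000):
            v[p] = 5.0
            src[p - 4 : p + 4] += shape
        v[3000] = 1.5  # marginal, but its segment is pure noise
        spikes, alphas = assign_alpha(v, 2.0, (1.0, 3.0), src, fs, corr_threshold=0.8)
        i = list(spikes).index(3000)
        assert alphas[i] == pytest.approx(0.9)


class TestGckcUpdate:
    def test_eta_zero_no_change(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((4, 30))
        f = MUFilter(r=np.ones(4))
        out = gckc_update(f, X, rng.standard_normal(30), 1.0, eta=0.0)
        assert np.array_equal(out.r, f.r)

    def test_zero_train_no_change(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((4, 30))
        f = MUFilter(r=np.ones(4))
        out = gckc_update(f, X, np.zeros(30), 1.0, eta=0.3)
        assert np.allclose(out.r, f.r)

    def test_matches_hand_evaluated_recursion(self):
        """One update equals the literal recursion on a 5-sample instance."""
        X = np.array([[1.0, -2.0, 0.5, 3.0, -1.0], [0.0, 1.0, 1.0, -1.0, 2.0]])
        t = np.array([0.1, -0.5, 2.0, 0.0, 1.0])
        alpha = np.array([1.0, 1.0, 0.9, 1.0, 1.0])
        r0 = np.array([0.3, -0.7])
        eta = 0.05
        # hand evaluation: r_g = r_{g-1} + eta * sum_m f(t_m) X(m)
        f_vals = alpha * np.log(1.0 + t**2)
        expected = r0 + eta * (X * f_vals).sum(axis=1)
        out = gckc_update(MUFilter(r=r0), X, t, alpha, eta)
        assert np.allclose(out.r, expected, rtol=1e-15, atol=1e-15)


class TestKalman:
    def _state(self, n, p=1.0, cw=1e-4):
        return KalmanState(r=np.zeros(n), p_diag=np.full(n + 1, p), sigma2=1.0, cw=cw)

    def test_zero_gain_returns_prediction(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((5, 200))
        t = rng.standard_normal(200)
        state = self._state(5, p=0.0, cw=0.0)
        new, t_pred = kalman_step(state, X, t, eta=0.1)
        grad = X @ (np.log1p(t**2))
        expected = state.r + 0.1 * grad / np.linalg.norm(grad)
        assert np.allclose(new.r, expected)

    def test_covariance_symmetric_psd_over_random_steps(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((6, 300))
        state = self._state(6)
        for _ in range(100):
            t = rng.standard_normal(300)
            target = np.zeros(300)
            target[rng.choice(300, 20, replace=False)] = 1.0
            state, _ = kalman_step(state, X, t, eta=0.1, target=target)
            P = state.P
            assert np.allclose(P, P.T)
            assert np.all(np.linalg.eigvalsh(P) >= 0)

    def test_gain_decays_and_sigma_tracked(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((6, 500))
        state = self._state(6)
        ps = []
        for _ in range(5):
            t = rng.standard_normal(500)
            state, _ = kalman_step(state, X, t, eta=0.05)
            ps.append(state.p_diag[0])
        assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(4))
        assert state.sigma2 > 0

    def test_kalman_tracks_target_filter_faster_than_gradient(self):
        """On a toy source-extraction problem the Kalman-updated filter is
        closer to the ideal (spike-triggered) filter after 10 iterations."""
        from gss_hdemg.preprocess import extend, whiten
        from gss_hdemg.simulate import ElectrodeGrid, EMGRecording

        data, trains, fs = _toy_mixture(seed=13)
        rec = EMGRecording(
            data=data, fs_hz=fs,
            grid=ElectrodeGrid(rows=data.shape[0], cols=1, ied_mm=5.0, fs_hz=fs),
        )
        obs = whiten(extend(rec, R=8))
        X = obs.X
        idx = np.round(trains[0] * fs).astype(int)
        r_star = X[:, idx].mean(axis=1)
        r_star /= np.linalg.norm(r_star)
        target = np.zeros(obs.M)
        target[idx] = 1.0

        def err(r):
            r = r / np.linalg.norm(r)
            return 1.0 - abs(float(r @ r_star))

        r0 = X[:, idx[3]] / np.linalg.norm(X[:, idx[3]])
        # gradient path
        rg = r0.copy()
        for g in range(1, 11):
            t = rg @ X
            t /= np.mean(np.partition(t, t.size - 10)[-10:])
            u = X @ np.log1p(t**2)
            rg = rg + 0.1 / (1 + g / 20) * u / np.linalg.norm(u)
            rg /= np.linalg.norm(rg)
        # Kalman path
        state = KalmanState(r=r0.copy(), p_diag=np.ones(X.shape[0] + 1),
                            sigma2=1.0, cw=1e-4)
        rk = r0.copy()
        for g in range(1, 11):
            t = rk @ X
            t /= np.mean(np.partition(t, t.size - 10)[-10:])
            state = KalmanState(r=rk, p_diag=state.p_diag, sigma2=state.sigma2,
                                cw=state.cw, k=state.k)
            state, _ = kalman_step(state, X, t, eta=0.1 / (1 + g / 20), target=target)
            rk = state.r / np.linalg.norm(state.r)
        assert err(rk) <= err(rg)


class TestDecomposeMu:
    def test_toy_mixture_recovered(self):
        from gss_hdemg.preprocess import extend, whiten
        from gss_hdemg.simulate import ElectrodeGrid, EMGRecording
        from gss_hdemg.validation import match_with_alignment

        data, trains, fs = _toy_mixture(seed=14)
        rec = EMGRecording(
            data=data, fs_hz=fs,
            grid=ElectrodeGrid(rows=data.shape[0], cols=1, ied_mm=5.0, fs_hz=fs),
        )
        obs = whiten(extend(rec, R=8))
        m0 = int(round(trains[1][4] * fs))
        point = InitialPoint(sample_index=m0, source_channel=0, provenance=0)
        cfg = GCKCConfig(use_kalman=True)
        est, filt, iters = decompose_mu(
            obs, point, cfg, source_signal=data[0], rng=np.random.default_rng(0)
        )
        times = est.firing_indices() / fs
        res, _ = match_with_alignment(times, trains[1], tol_s=1.5 / fs)
        assert res.roa >= 0.9

    def test_max_iters_one_single_update(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((8, 2000))
        X[:, 100] += 5.0
        obs = _obs(X)
        point = InitialPoint(sample_index=100, source_channel=0, provenance=0)
        est, filt, iters = decompose_mu(
            obs, point, GCKCConfig(max_iters=1, n_boot=0), rng=rng
        )
        assert iters == 1

    def test_divergence_reported(self):
        obs = _obs(np.zeros((3, 500)))
        point = InitialPoint(sample_index=5, source_channel=0, provenance=0)
        from gss_hdemg.gss_core import DecompositionError

        with pytest.raises(DecompositionError):
            decompose_mu(obs, point, GCKCConfig(), rng=np.random.default_rng(0))
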