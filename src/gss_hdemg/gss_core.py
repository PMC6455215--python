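"""Gradient Convolution Kernel Compensation with EM-Kalman acceleration.

The CKC estimator reconstructs the spike train of one motor unit as
``t = r' Rxx^{-1} X`` where ``r`` is the cross-correlation vector between the
extended/whitened observations ``X`` and the (unknown) spike train.  ``r`` is
refined iteratively:

* plain gradient update ``r <- r + eta(g) X f(t)`` with the attenuated
  contrast ``f(x) = alpha(x) log(1 + x^2)``;
* adaptive soft-thresholding: after every iteration a spike-detection
  threshold maximizing the pulse-to-noise ratio (PNR) is found by greedy
  search; spikes inside the 95% CI band of the threshold are *marginal* and
  are attenuated (``alpha = 0.9``) unless their 2-ms EMG segment correlates
  with the template of the confident spikes;
* EM-Kalman acceleration: the gradient recursion is embedded in a
  state-space model whose observation noise variance is re-estimated each
  iteration (EM step); the Kalman gain shrinks as the state covariance
  contracts, which damps noise amplification and speeds up convergence.

The error covariance ``P`` of the Kalman state is maintained as a diagonal
matrix, which keeps every update O(N·M) while preserving symmetry and
positive semidefiniteness; see docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .initpoints import InitialPoint
from .preprocess import ExtendedObservation

__all__ = [
    "MUFilter",
    "SpikeTrainEstimate",
    "KalmanState",
    "GCKCConfig",
    "DecompositionError",
    "ckc_estimate",
    "init_filter",
    "pnr",
    "optimize_threshold",
    "assign_alpha",
    "gckc_update",
    "kalman_step",
    "decompose_mu",
    "GSSDecomposer",
]


class DecompositionError(RuntimeError):
    """Raised when the iteration for one MU diverges."""


@dataclass
class MUFilter:
    """Cross-correlation vector ("MU filter") and its iteration state."""

    r: np.ndarray
    iteration: int = 0
    eta: float = 0.0


@dataclass
class SpikeTrainEstimate:
    """Continuous-valued spike-train estimate with its detection state."""

    values: np.ndarray
    thr: float
    thr_ci: tuple[float, float]
    pnr_db: float
    spike_indices: np.ndarray
    spike_alphas: np.ndarray
    fs_hz: float

    def firing_indices(self) -> np.ndarray:
        """Detected firings kept by the soft threshold (alpha == 1)."""
        return self.spike_indices[self.spike_alphas >= 1.0]


@dataclass
class KalmanState:
    """Diagonal-covariance EM-Kalman state ``x = [r; 1]``."""

    r: np.ndarray
    p_diag: np.ndarray  # length N + 1
    sigma2: float
    cw: float
    k: int = 0

    @property
    def P(self) -> np.ndarray:
        return np.diag(self.p_diag)


@dataclass
class GCKCConfig:
    eta0: float = 0.1
    eta_tau: float = 20.0
    max_iters: int = 150
    min_iters: int = 6
    stop_patience: int = 3
    pnr_tol_db: float = 0.1
    pnr_patience: int = 5
    corr_threshold: float = 0.8
    use_kalman: bool = True
    adaptive_alpha: bool = True
    cw: float = 1e-4
    p_floor: float = 1e-4
    fp_init: int = 1  # fixed-point (spike-triggered) initialization passes
    fp_gate: float = 0.6  # fraction of the optimal threshold used at init
    min_rate_hz: float = 4.0  # spike-rate floor for the threshold search
    refractory_ms: float = 8.0
    n_boot: int = 200
    n_candidates: int = 24
    pnr_squared: bool = True

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")

    def eta(self, g: int) -> float:
        return self.eta0 / (1.0 + g / self.eta_tau)


# ---------------------------------------------------------------------------
# estimator and contrast


def ckc_estimate(obs: ExtendedObservation, filt: MUFilter | np.ndarray) -> np.ndarray:
    """``t = r' Rxx^{-1} X`` (identity correlation once whitened)."""
    r = filt.r if isinstance(filt, MUFilter) else np.asarray(filt)
    if obs.whitening is not None:
        return r @ obs.X
    return (r @ obs.Rxx_inv) @ obs.X


def init_filter(obs: ExtendedObservation, point: InitialPoint) -> MUFilter:
    """Initialize the MU filter with the observation column at the point."""
    idx = point.sample_index
    if not (0 <= idx < obs.M):
        raise ValueError(f"initial point {idx} outside [0, {obs.M})")
    return MUFilter(r=obs.X[:, idx].copy())


def _f(x: np.ndarray, alpha: np.ndarray | float) -> np.ndarray:
    return alpha * np.log1p(x**2)


def _f_prime(x: np.ndarray, alpha: np.ndarray | float) -> np.ndarray:
    return alpha * 2.0 * x / (1.0 + x**2)


def _unit_spike_scale(t: np.ndarray, k: int = 10) -> float:
    """Scale that brings the mean of the k largest samples to 1.

    The CKC reconstruction targets the binary firing train, so estimates are
    kept with spike peaks near unity, where the contrast ``f`` and its
    derivative are maximally spike-selective.
    """
    if t.size <= k:
        return float(np.max(t)) if t.size else 1.0
    tops = np.partition(t, t.size - k)[-k:]
    s = float(np.mean(tops))
    return s if s > 0 else 1.0


# ---------------------------------------------------------------------------
# PNR and threshold search


def pnr(values: np.ndarray, thr: float, squared: bool = True) -> float:
    """Pulse-to-noise ratio in dB of the split at ``thr``.

    With ``squared`` (default) the ratio compares mean squared sample values
    of the spike class (``values >= thr``) against the baseline class.
    """
    v = np.asarray(values, dtype=float)
    above = v >= thr
    if not above.any() or above.all():
        return float("nan")
    num = v[above] ** 2 if squared else v[above]
    den = v[~above] ** 2 if squared else v[~above]
    return float(10.0 * np.log10(np.mean(num) / np.mean(den)))


def _pnr_at_thresholds(sorted_vals: np.ndarray, cumsq: np.ndarray, thr: np.ndarray) -> np.ndarray:
    """Vectorized PNR for many thresholds on one pre-sorted sample vector."""
    n = sorted_vals.size
    idx = np.searchsorted(sorted_vals, thr)
    idx = np.clip(idx, 1, n - 1)
    below = cumsq[idx - 1] / idx
    above = (cumsq[-1] - cumsq[idx - 1]) / (n - idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 10.0 * np.log10(above / below)


def optimize_threshold(
    values: np.ndarray,
    rng: np.random.Generator | None = None,
    n_candidates: int = 24,
    n_boot: int = 200,
    min_spikes: int = 0,
) -> tuple[float, tuple[float, float], float]:
    """PNR-maximizing spike-detection threshold with a bootstrap 95% CI.

    Candidate thresholds are quantiles of the local-maximum amplitudes of
    ``values``; the greedy search returns the candidate with the highest PNR.
    ``min_spikes`` restricts the search to thresholds keeping at least that
    many peaks — a physiological floor on the discharge rate that prevents
    the energy ratio from locking onto a handful of extreme peaks.  The CI
    comes from re-running the search on ``n_boot`` bootstrap resamples of
    the detected peak amplitudes.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4 or np.ptp(v) == 0:
        raise ValueError("degenerate spike-train estimate; cannot optimize threshold")
    rng = np.random.default_rng() if rng is None else rng
    peaks, _ = sps.find_peaks(v)
    heights = v[peaks]
    heights = heights[heights > 0]
    if heights.size < 3:
        heights = np.sort(v)[-max(3, v.size // 100) :]
    # candidate grid dense in the upper tail: spikes are a small fraction of
    # all local maxima, so the informative thresholds sit above the ~90th
    # percentile of peak amplitudes
    q = 1.0 - np.geomspace(0.5, 0.005, n_candidates)
    sorted_heights = np.sort(heights)
    sorted_vals = np.sort(v)
    cumsq = np.cumsum(sorted_vals**2)

    def search(cand_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Constrained argmax over candidate rows (n_rows, n_candidates)."""
        flat = cand_rows.ravel()
        scores = _pnr_at_thresholds(sorted_vals, cumsq, flat).reshape(cand_rows.shape)
        if min_spikes > 0:
            n_above = sorted_heights.size - np.searchsorted(sorted_heights, flat)
            bad = (n_above < min_spikes).reshape(cand_rows.shape)
            # rows with no admissible candidate fall back to the lowest one
            bad[bad.all(axis=1), 0] = False
            scores = np.where(bad, -np.inf, scores)
        scores = np.where(np.isnan(scores), -np.inf, scores)
        best = np.argmax(scores, axis=1)
        rows = np.arange(cand_rows.shape[0])
        return cand_rows[rows, best], scores[rows, best]

    thr_arr, pnr_arr = search(np.quantile(heights, q)[None, :])
    thr, best_pnr = float(thr_arr[0]), float(pnr_arr[0])
    if n_boot > 0 and heights.size >= 3:
        resamples = rng.choice(heights, size=(n_boot, heights.size), replace=True)
        cand_b = np.quantile(resamples, q, axis=1).T  # (n_boot, n_candidates)
        thr_b, _ = search(cand_b)
        lo, hi = np.percentile(thr_b, [2.5, 97.5])
        lo, hi = min(lo, thr), max(hi, thr)
    else:
        lo, hi = thr, thr
    return thr, (float(lo), float(hi)), best_pnr


# ---------------------------------------------------------------------------
# adaptive soft-thresholding


def assign_alpha(
    values: np.ndarray,
    thr: float,
    ci95: tuple[float, float],
    source_signal: np.ndarray | None,
    fs: float,
    corr_threshold: float = 0.8,
    win_ms: float = 2.0,
    refractory_ms: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spike attenuation for the soft threshold.

    Spikes above the upper CI bound are confident (``alpha = 1``).  Marginal
    spikes (inside the CI band) keep ``alpha = 1`` only when the Pearson
    correlation between their 2-ms EMG segment and the template of the
    confident spikes reaches ``corr_threshold``; otherwise ``alpha = 0.9``.

    Returns the sorted spike sample indices and their alphas.
    """
    lo, hi = ci95
    v = np.asarray(values, dtype=float)
    dist = max(1, int(round(refractory_ms * 1e-3 * fs)))
    peaks, _ = sps.find_peaks(v, height=min(lo, thr), distance=dist)
    if peaks.size == 0:
        return peaks, np.empty(0)
    alphas = np.ones(peaks.size)
    marginal = v[peaks] < hi
    if not marginal.any() or source_signal is None:
        return peaks, alphas
    half = max(2, int(round(win_ms * 1e-3 * fs / 2)))
    sig = np.asarray(source_signal, dtype=float)

    def _window(p: int) -> np.ndarray | None:
        if p - half < 0 or p + half > sig.size:
            return None
        return sig[p - half : p + half]

    confident = peaks[~marginal]
    wins = [w for p in confident if (w := _window(int(p))) is not None]
    if not wins:
        alphas[marginal] = 0.9
        return peaks, alphas
    template = np.mean(wins, axis=0)
    t0 = template - template.mean()
    tn = np.linalg.norm(t0)
    for i in np.flatnonzero(marginal):
        w = _window(int(peaks[i]))
        if w is None:
            alphas[i] = 0.9
            continue
        w0 = w - w.mean()
        denom = tn * np.linalg.norm(w0)
        rho = float(w0 @ t0 / denom) if denom > 0 else 0.0
        alphas[i] = 1.0 if rho >= corr_threshold else 0.9
    return peaks, alphas


def _alpha_signal(m: int, spikes: np.ndarray, alphas: np.ndarray, dtype=np.float64) -> np.ndarray:
    a = np.ones(m, dtype=dtype)
    if spikes.size:
        a[spikes] = alphas
    return a


# ---------------------------------------------------------------------------
# updates


def gckc_update(
    filt: MUFilter,
    X: np.ndarray,
    values: np.ndarray,
    alpha: np.ndarray | float,
    eta: float,
) -> MUFilter:
    """One gradient step ``r <- r + eta · X f(t)`` with per-sample alpha."""
    r = filt.r + eta * (X @ _f(values, alpha))
    return MUFilter(r=r, iteration=filt.iteration + 1, eta=eta)


def kalman_step(
    state: KalmanState,
    X: np.ndarray,
    values_prev: np.ndarray,
    eta: float,
    alpha: np.ndarray | float = 1.0,
    target: np.ndarray | None = None,
    p_floor: float = 1e-4,
) -> tuple[KalmanState, np.ndarray]:
    """One EM-Kalman iteration of the state ``x = [r; 1]``.

    Predict with the gradient-embedding system matrix (the last column
    carries the gradient-CKC increment, normalized like the plain gradient
    step).  The measurement is the soft-thresholded spike train ``target``
    detected in the current iteration — the algorithm's current belief
    about the underlying binary firing train.  The EM step re-estimates the
    observation-noise variance from the innovation, and the Kalman gain
    ``p / (p + sigma^2)`` blends the predicted filter with the
    least-squares filter reproducing the target (for whitened observations
    ``X target / M``).  The error covariance is isotropic (``P = p I``,
    trivially symmetric PSD) and contracts by ``1 − gain`` each iteration,
    so early iterations take large steps toward the detected train and
    later iterations settle; ``p_floor`` keeps ``P`` positive definite.

    When ``target`` is None the innovation is taken against
    ``values_prev`` (pure tracking).  Returns the updated state and the
    predicted spike train.
    """
    n, m = X.shape
    grad = X @ _f(values_prev, alpha)
    gn = np.linalg.norm(grad)
    b = eta * grad / gn if gn > 0 else grad
    r_pred = state.r + b
    p = float(state.p_diag[0]) + state.cw**2
    t_pred = r_pred @ X
    t_pred = t_pred / _unit_spike_scale(t_pred)  # same scale as values_prev
    obs_train = values_prev if target is None else target
    innov = obs_train - t_pred
    sigma2 = max(float(np.mean(innov**2)), 1e-12)
    gain = p / (p + sigma2)
    r_ls = X @ obs_train
    nrm_ls = np.linalg.norm(r_ls)
    if nrm_ls > 0:
        r_ls = r_ls * (np.linalg.norm(r_pred) / nrm_ls)
        r_new = (1.0 - gain) * r_pred + gain * r_ls
    else:
        r_new = r_pred
    p_new = max((1.0 - gain) * p + state.cw**2, p_floor)
    new_state = KalmanState(
        r=r_new,
        p_diag=np.full(n + 1, p_new),
        sigma2=sigma2,
        cw=state.cw,
        k=state.k + 1,
    )
    return new_state, t_pred


# ---------------------------------------------------------------------------
# per-MU decomposition loop


def decompose_mu(
    obs: ExtendedObservation,
    point: InitialPoint,
    cfg: GCKCConfig,
    source_signal: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SpikeTrainEstimate, MUFilter, int]:
    """Full iterative estimation of one MU spike train from one initial point.

    ``init_filter`` → one plain gradient iteration → iterate
    {estimate → PNR-optimal threshold → soft-threshold alphas →
    Kalman or gradient update} until the detected firing set is stable for
    ``stop_patience`` iterations, the PNR plateaus, or ``max_iters`` is hit.
    """
    rng = np.random.default_rng() if rng is None else rng
    X = obs.X
    m = obs.M
    filt = init_filter(obs, point)
    r_norm = np.linalg.norm(filt.r)
    if not np.isfinite(r_norm) or r_norm == 0:
        raise DecompositionError("initial observation column has zero energy")
    r = filt.r / r_norm

    def estimate(r_vec: np.ndarray) -> np.ndarray:
        t = r_vec @ X
        return t / _unit_spike_scale(t)

    min_spikes = int(cfg.min_rate_hz * m / obs.fs_hz)

    # fixed-point start: spike-triggered re-initialization of the filter
    # from the peaks of the initial-point estimate
    dist = max(1, int(round(cfg.refractory_ms * 1e-3 * obs.fs_hz)))
    for _ in range(max(0, cfg.fp_init)):
        t = estimate(r)
        try:
            thr0, _, _ = optimize_threshold(t, rng, cfg.n_candidates, 0, min_spikes)
        except ValueError:
            break
        spikes0, _ = sps.find_peaks(t, height=cfg.fp_gate * thr0, distance=dist)
        if spikes0.size < 3:
            break
        r_new = X[:, spikes0].mean(axis=1)
        nrm = np.linalg.norm(r_new)
        if nrm == 0:
            break
        r = r_new / nrm

    # one plain gCKC iteration (alpha == 1) to form the first state
    t = estimate(r)
    u = X @ _f(t, 1.0)
    un = np.linalg.norm(u)
    r = r + cfg.eta(1) * (u / un if un > 0 else u)
    nrm = np.linalg.norm(r)
    if not np.isfinite(nrm) or nrm == 0:
        raise DecompositionError("filter diverged during initialization")
    r /= nrm
    iterations = 1
    state = KalmanState(r=r, p_diag=np.ones(X.shape[0] + 1), sigma2=1.0, cw=cfg.cw)

    set_hist: list[frozenset] = []
    pnr_hist: list[float] = []
    last = None
    for g in range(2, cfg.max_iters + 1):
        t = estimate(r)
        if not np.all(np.isfinite(t)):
            raise DecompositionError("spike-train estimate diverged")
        try:
            thr, ci, pnr_db = optimize_threshold(
                t, rng, cfg.n_candidates, cfg.n_boot, min_spikes
            )
        except ValueError as exc:
            raise DecompositionError(str(exc)) from exc
        if cfg.adaptive_alpha:
            spikes, alphas = assign_alpha(
                t, thr, ci, source_signal, obs.fs_hz, cfg.corr_threshold,
                refractory_ms=cfg.refractory_ms,
            )
        else:
            dist = max(1, int(round(cfg.refractory_ms * 1e-3 * obs.fs_hz)))
            spikes, _ = sps.find_peaks(t, height=thr, distance=dist)
            alphas = np.ones(spikes.size)
        last = (t, thr, ci, pnr_db, spikes, alphas)
        firing_set = frozenset(spikes[alphas >= 1.0].tolist())
        set_hist.append(firing_set)
        pnr_hist.append(pnr_db)
        if g > cfg.min_iters:
            if len(set_hist) >= cfg.stop_patience and all(
                s == set_hist[-1] for s in set_hist[-cfg.stop_patience :]
            ):
                break
            if (
                len(pnr_hist) > cfg.pnr_patience
                and pnr_hist[-1] - pnr_hist[-1 - cfg.pnr_patience] < cfg.pnr_tol_db
            ):
                break

        a_sig = _alpha_signal(m, spikes, alphas, X.dtype)
        if cfg.use_kalman:
            target = np.zeros(m, dtype=X.dtype)
            if spikes.size:
                target[spikes] = alphas
            state = replace(state, r=r)
            state, _ = kalman_step(
                state, X, t, cfg.eta(g), a_sig, target, cfg.p_floor
            )
            r = state.r
        else:
            u = X @ _f(t, a_sig)
            un = np.linalg.norm(u)
            r = r + cfg.eta(g) * (u / un if un > 0 else u)
        nrm = np.linalg.norm(r)
        if not np.isfinite(nrm) or nrm == 0:
            raise DecompositionError("filter diverged")
        r /= nrm
        if cfg.use_kalman:
            state = replace(state, r=r)  # covariance is in measurement units
        iterations += 1

    if last is None:  # max_iters == 1: only the initialization pass ran
        t = estimate(r)
        try:
            thr, ci, pnr_db = optimize_threshold(
                t, rng, cfg.n_candidates, cfg.n_boot, min_spikes
            )
        except ValueError as exc:
            raise DecompositionError(str(exc)) from exc
        spikes, alphas = assign_alpha(
            t, thr, ci, source_signal, obs.fs_hz, cfg.corr_threshold,
            refractory_ms=cfg.refractory_ms,
        )
        last = (t, thr, ci, pnr_db, spikes, alphas)

    t, thr, ci, pnr_db, spikes, alphas = last
    est = SpikeTrainEstimate(
        values=t,
        thr=thr,
        thr_ci=ci,
        pnr_db=pnr_db,
        spike_indices=spikes,
        spike_alphas=alphas,
        fs_hz=obs.fs_hz,
    )
    return est, MUFilter(r=r, iteration=iterations, eta=cfg.eta(iterations)), iterations


class GSSDecomposer(BaseEstimator):
    """Guided-source-separation engine over a whitened extended observation.

    ``fit`` runs :func:`decompose_mu` from every initial point.  Failed
    points (divergent or degenerate) are skipped and recorded.

    Attributes
    ----------
    estimates_ : list of SpikeTrainEstimate
    filters_ : list of MUFilter
    iterations_ : list of int
    point_ids_ : list of int
        Index into the supplied initial-point list for each estimate.
    """

    def __init__(
        self,
        use_kalman: bool = True,
        adaptive_alpha: bool = True,
        eta0: float = 0.1,
        eta_tau: float = 20.0,
        max_iters: int = 150,
        stop_patience: int = 3,
        pnr_tol_db: float = 0.1,
        pnr_patience: int = 5,
        corr_threshold: float = 0.8,
        cw: float = 1e-4,
        n_boot: int = 200,
        random_state: int | None = 0,
    ):
        self.use_kalman = use_kalman
        self.adaptive_alpha = adaptive_alpha
        self.eta0 = eta0
        self.eta_tau = eta_tau
        self.max_iters = max_iters
        self.stop_patience = stop_patience
        self.pnr_tol_db = pnr_tol_db
        self.pnr_patience = pnr_patience
        self.corr_threshold = corr_threshold
        self.cw = cw
        self.n_boot = n_boot
        self.random_state = random_state

    def _config(self) -> GCKCConfig:
        return GCKCConfig(
            eta0=self.eta0,
            eta_tau=self.eta_tau,
            max_iters=self.max_iters,
            stop_patience=self.stop_patience,
            pnr_tol_db=self.pnr_tol_db,
            pnr_patience=self.pnr_patience,
            corr_threshold=self.corr_threshold,
            use_kalman=self.use_kalman,
            adaptive_alpha=self.adaptive_alpha,
            cw=self.cw,
            n_boot=self.n_boot,
        )

    def fit(
        self,
        obs: ExtendedObservation,
        initial_points: list[InitialPoint],
        source_data: np.ndarray | None = None,
    ) -> "GSSDecomposer":
        cfg = self._config()
        self.estimates_, self.filters_, self.iterations_, self.point_ids_ = [], [], [], []
        self.failures_ = []
        for i, point in enumerate(initial_points):
            rng = np.random.default_rng(
                None if self.random_state is None else (self.random_state + 7919 * i) % (2**31)
            )
            src = None
            if source_data is not None:
                src = source_data[point.source_channel]
            try:
                est, filt, iters = decompose_mu(obs, point, cfg, src, rng)
            except DecompositionError as exc:
                self.failures_.append((i, str(exc)))
                continue
            self.estimates_.append(est)
            self.filters_.append(filt)
            self.iterations_.append(iters)
            self.point_ids_.append(i)
        return self
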