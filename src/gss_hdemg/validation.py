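"""Scoring against ground truth and signal-based quality indices.

Firing-train accuracy uses the signal-detection convention: a true positive
is an estimated firing matching a simulated firing within ±0.5 ms
(one-to-one, greedy nearest-first).  The rate of agreement
``RoA = TP/(TP+FN+FP)``, sensitivity ``TP/(TP+FN)`` and precision
``TP/(TP+FP)`` summarize each match.  A MU counts as *identified* when at
least 30% of its simulated firings are time-locked within the tolerance.

Signal-based indices: the signal-to-interference ratio (SIR) is the
percentage of single-differential EMG variance explained by the
reconstruction from spike-triggered-average MUAPs, and the decomposability
index ``DI = min(||m||, ||m - m*||) / V_rms`` measures how distinct each
MUAP is from its nearest competitor relative to the channel noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mu_post import FiringPattern, best_lag_matches
from .simulate import EMGRecording, GroundTruth

__all__ = [
    "MatchResult",
    "QualityIndices",
    "match_firings",
    "match_with_alignment",
    "is_identified",
    "cluster_correct",
    "sta_muap",
    "sir",
    "decomposability",
    "score_decomposition",
]


@dataclass
class MatchResult:
    est_mu: int
    true_mu: int
    tp: int
    fp: int
    fn: int

    @property
    def roa(self) -> float:
        d = self.tp + self.fn + self.fp
        return self.tp / d if d else 0.0

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0


@dataclass
class QualityIndices:
    sir_percent: np.ndarray  # per channel
    sir_mean: float
    di: np.ndarray | None = None  # per MU × channel
    cdi: np.ndarray | None = None  # per MU


def match_firings(
    est_times: np.ndarray,
    truth_times: np.ndarray,
    tol_s: float = 0.5e-3,
    est_mu: int = -1,
    true_mu: int = -1,
) -> MatchResult:
    """Greedy nearest-first one-to-one matching within ±tol (no alignment)."""
    a = np.sort(np.asarray(est_times, dtype=float))
    b = np.sort(np.asarray(truth_times, dtype=float))
    pairs = []
    j0 = np.searchsorted(b, a - tol_s)
    j1 = np.searchsorted(b, a + tol_s)
    for i in range(a.size):
        for j in range(j0[i], j1[i]):
            d = abs(a[i] - b[j])
            if d <= tol_s:
                pairs.append((d, a[i], i, j))
    pairs.sort()  # by distance, ties toward the earlier firing
    used_a = np.zeros(a.size, dtype=bool)
    used_b = np.zeros(b.size, dtype=bool)
    tp = 0
    for _, _, i, j in pairs:
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            tp += 1
    return MatchResult(est_mu=est_mu, true_mu=true_mu, tp=tp, fp=a.size - tp, fn=b.size - tp)


def match_with_alignment(
    est_times: np.ndarray,
    truth_times: np.ndarray,
    tol_s: float = 0.5e-3,
    max_lag_s: float = 0.015,
    est_mu: int = -1,
    true_mu: int = -1,
) -> tuple[MatchResult, float]:
    """Matching after removing the best constant time shift of the estimate."""
    _, lag = best_lag_matches(np.sort(est_times), np.sort(truth_times), tol_s, max_lag_s)
    res = match_firings(np.asarray(est_times) + lag, truth_times, tol_s, est_mu, true_mu)
    return res, lag


def is_identified(match: MatchResult, truth_count: int, quota: float = 0.30) -> bool:
    """At least ``quota`` of the simulated firings time-locked within tol."""
    if truth_count <= 0:
        raise ValueError("truth_count must be positive")
    return match.tp / truth_count >= quota


def cluster_correct(
    proxy_times: np.ndarray,
    truth: GroundTruth | dict[int, np.ndarray],
    quota: float = 0.75,
    tol_s: float = 0.5e-3,
    max_lag_s: float = 0.015,
) -> bool:
    """Is a cluster time-locked (≥ quota of its proxies) to one simulated MU?"""
    proxies = np.sort(np.asarray(proxy_times, dtype=float))
    if proxies.size == 0:
        raise ValueError("no cluster proxies")
    trains = truth.firing_times if isinstance(truth, GroundTruth) else truth
    best = 0.0
    for times in trains.values():
        n, _ = best_lag_matches(proxies, np.sort(times), tol_s, max_lag_s)
        best = max(best, n / proxies.size)
    return best >= quota


def sta_muap(
    rec: EMGRecording, firing_times: np.ndarray, half_window: int
) -> np.ndarray:
    """Spike-triggered average MUAP, channels × (2·half_window + 1)."""
    t = np.asarray(firing_times, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 firings for spike-triggered averaging")
    idx = np.round(t * rec.fs_hz).astype(int)
    keep = (idx - half_window >= 0) & (idx + half_window < rec.n_samples)
    idx = idx[keep]
    if idx.size == 0:
        raise ValueError("all spike-triggered windows cross the recording bounds")
    wins = np.stack([rec.data[:, i - half_window : i + half_window + 1] for i in idx])
    return wins.mean(axis=0)


def _reconstruct(
    rec: EMGRecording, patterns: list[FiringPattern], templates: list[np.ndarray]
) -> np.ndarray:
    recon = np.zeros_like(rec.data)
    for pat, tpl in zip(patterns, templates):
        half = (tpl.shape[1] - 1) // 2
        idx = np.round(pat.firing_times * rec.fs_hz).astype(int)
        for i in idx:
            lo, hi = i - half, i + half + 1
            a = max(lo, 0)
            b = min(hi, rec.n_samples)
            if a >= b:
                continue
            recon[:, a:b] += tpl[:, a - lo : tpl.shape[1] - (hi - b)]
    return recon


def sir(
    rec_sd: EMGRecording,
    patterns: list[FiringPattern],
    templates: list[np.ndarray] | None = None,
    half_window: int | None = None,
) -> QualityIndices:
    """Signal-to-interference ratio of the decomposition per channel.

    Each channel is reconstructed as the sum of MUAP templates (by default
    spike-triggered averages) convolved with the estimated firing trains:
    ``SIR(i) = (1 - E[(x_i - sum_j z_ij)^2] / E[x_i^2]) × 100``.
    """
    if rec_sd.montage != "single_differential":
        raise ValueError("SIR is defined on single-differential signals")
    if half_window is None:
        half_window = int(round(0.010 * rec_sd.fs_hz))
    if templates is None:
        templates = []
        usable = []
        for pat in patterns:
            try:
                templates.append(sta_muap(rec_sd, pat.firing_times, half_window))
                usable.append(pat)
            except ValueError:
                continue
        patterns = usable
    recon = _reconstruct(rec_sd, patterns, templates)
    p_sig = np.mean(rec_sd.data**2, axis=1)
    p_res = np.mean((rec_sd.data - recon) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (1.0 - p_res / p_sig) * 100.0
    s = np.where(p_sig > 0, s, 0.0)
    return QualityIndices(sir_percent=s, sir_mean=float(np.mean(s)))


def decomposability(
    templates: list[np.ndarray],
    noise_rms: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Decomposability indices ``DI_ki`` and their channel-normalized sums.

    For MU ``k`` and channel ``i``, ``DI_ki = min(||m_ki||, ||m_ki − m_k*i||)
    / V_i_rms`` where ``m_k*i`` is the channel-``i`` MUAP of the nearest
    competitor MU.  ``cDI_k`` aggregates over channels, normalized by the
    channel count.  With no competitor the second argument of ``min`` drops.
    """
    noise_rms = np.asarray(noise_rms, dtype=float)
    if np.any(noise_rms <= 0):
        raise ValueError("noise_rms must be positive")
    k = len(templates)
    if k == 0:
        return np.empty((0, noise_rms.size)), np.empty(0)
    n_ch = templates[0].shape[0]
    di = np.empty((k, n_ch))
    for a in range(k):
        for i in range(n_ch):
            m = templates[a][i]
            own = np.linalg.norm(m)
            best_diff = np.inf
            for b in range(k):
                if b == a:
                    continue
                diff = np.linalg.norm(m - templates[b][i])
                best_diff = min(best_diff, diff)
            di[a, i] = min(own, best_diff) / noise_rms[i]
    cdi = di.sum(axis=1) / n_ch
    return di, cdi


def score_decomposition(
    patterns: list[FiringPattern],
    truth: GroundTruth,
    tol_s: float = 0.5e-3,
    quota: float = 0.30,
    scoreable_only: bool = True,
    max_lag_s: float = 0.015,
) -> list[dict]:
    """Match every estimated pattern to its best simulated MU.

    For each pattern the simulated MU maximizing the aligned TP count is
    selected; the record carries the match ratios, the identification flag
    and the firing-statistics biases (estimate − truth) for MDR and ISI CoV.
    """
    from .mu_post import firing_stats

    ids = truth.scoreable_mu_ids if scoreable_only and truth.scoreable_mu_ids else truth.active_mu_ids
    out = []
    for pat in patterns:
        best = None
        for mu_id in ids:
            tt = truth.firing_times[mu_id]
            res, lag = match_with_alignment(
                pat.firing_times, tt, tol_s, max_lag_s, est_mu=pat.mu_id, true_mu=mu_id
            )
            if best is None or res.tp > best[0].tp:
                best = (res, lag, mu_id)
        if best is None:
            continue
        res, lag, mu_id = best
        tt = truth.firing_times[mu_id]
        true_pat = firing_stats(FiringPattern(mu_id=mu_id, firing_times=np.sort(tt)))
        out.append(
            {
                "est_mu": pat.mu_id,
                "true_mu": mu_id,
                "tp": res.tp,
                "fp": res.fp,
                "fn": res.fn,
                "roa": res.roa,
                "sensitivity": res.sensitivity,
                "precision": res.precision,
                "identified": is_identified(res, tt.size, quota),
                "lag_s": lag,
                "pnr_db": pat.pnr_db,
                "mdr_est_hz": pat.mdr_hz,
                "mdr_true_hz": true_pat.mdr_hz,
                "mdr_bias_hz": pat.mdr_hz - true_pat.mdr_hz,
                "cov_est": pat.cov_isi,
                "cov_true": true_pat.cov_isi,
                "cov_bias": pat.cov_isi - true_pat.cov_isi,
            }
        )
    return out
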