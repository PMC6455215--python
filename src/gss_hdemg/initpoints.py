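"""Template-side initialization of the decomposition.

Each channel is up-sampled to 10 kHz, segmented into 2-ms *active segments*
(AcSs) above an adaptive detection threshold, the segments are aligned on
their highest peak with sub-sample precision, and a density-based OPTICS
ordering (with the neighborhood radius set to infinity, so every point is a
core point) exposes clusters of similar MUAP shapes as reachability-distance
valleys.  The valley representatives, decimated back to the decomposition
sampling rate, become the initial points of the gradient-CKC search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .simulate import EMGRecording

__all__ = [
    "ActiveSegment",
    "OpticsOrdering",
    "ClusterRepresentative",
    "InitialPoint",
    "upsample",
    "detection_threshold",
    "detect_active_segments",
    "align_segments",
    "optics_order",
    "extract_valleys",
    "representatives_to_initial_points",
    "InitialPointEstimator",
]


@dataclass
class ActiveSegment:
    """A 2-ms window whose peak magnitude exceeds the detection threshold."""

    channel: int
    window: tuple[int, int]  # half-open sample interval at the upsampled rate
    peak_time: float  # seconds, sub-sample precision after alignment
    waveform: np.ndarray
    fs: float = 10000.0


@dataclass
class OpticsOrdering:
    order: np.ndarray  # permutation of segment indices
    reachability: np.ndarray  # RD per ordered point; first entry is +inf
    min_pts: int


@dataclass
class ClusterRepresentative:
    segment: ActiveSegment
    valley: tuple[int, int]  # half-open interval of ordered indices
    rd_at_rep: float
    member_order_idx: np.ndarray | None = None  # ordered positions in the valley


@dataclass
class InitialPoint:
    sample_index: int  # at the decomposition sampling rate
    source_channel: int
    provenance: int  # cluster id


def upsample(rec: EMGRecording, target_hz: float = 10000.0) -> EMGRecording:
    """Band-limited (Fourier zero-insertion) resampling with edge padding.

    The signal is reflected at both ends before the FFT resampling and
    cropped afterwards, which suppresses the wrap-around end effects of the
    zero-insertion method.
    """
    if target_hz <= rec.fs_hz:
        raise ValueError("target rate must exceed the current rate")
    m = rec.n_samples
    pad = min(m, max(64, int(0.016 * rec.fs_hz)))
    padded = np.concatenate(
        [rec.data[:, pad:0:-1], rec.data, rec.data[:, -2 : -pad - 2 : -1]], axis=1
    )
    n_out = int(round(padded.shape[1] * target_hz / rec.fs_hz))
    res = sps.resample(padded, n_out, axis=1)
    start = int(round(pad * target_hz / rec.fs_hz))
    stop = start + int(round(m * target_hz / rec.fs_hz))
    return rec.copy_with(data=res[:, start:stop], fs_hz=target_hz)


def detection_threshold(samples: np.ndarray, K: float = 4.0) -> float:
    """Adaptive amplitude threshold from the sorted-magnitude profile.

    Sort the magnitudes ascending (``s``), form the running RMS ``ss`` of the
    sorted values, and return ``s(i*)`` for the largest index where
    ``K · ss(i) > s(i)``.  On pure noise the running RMS approaches the noise
    RMS while ``s`` keeps growing into the spike tail, so the crossing sits
    near ``K`` times the baseline level.
    """
    x = np.abs(np.asarray(samples, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("empty input")
    if not np.any(x > 0):
        warnings.warn("all-zero input; detection threshold is 0")
        return 0.0
    s = np.sort(x)
    ss = np.sqrt(np.cumsum(s**2) / np.arange(1, s.size + 1))
    ok = np.nonzero(K * ss > s)[0]
    if ok.size == 0:
        return float(s[-1])
    return float(s[ok[-1]])


def detect_active_segments(
    samples: np.ndarray,
    thr: float,
    fs: float = 10000.0,
    win_ms: float = 2.0,
    channel: int = 0,
) -> list[ActiveSegment]:
    """Non-overlapping 2-ms windows centered on magnitude peaks above ``thr``.

    Window collisions are resolved toward the larger peak; windows that do
    not fit entirely inside the signal are dropped.
    """
    if thr < 0:
        raise ValueError("threshold must be non-negative")
    x = np.asarray(samples, dtype=float)
    win = max(2, int(round(win_ms * 1e-3 * fs)))
    half = win // 2
    peaks, _ = sps.find_peaks(np.abs(x), height=thr, distance=win)
    out = []
    for p in peaks:
        lo, hi = p - half, p - half + win
        if lo < 0 or hi > x.size:
            continue
        out.append(
            ActiveSegment(
                channel=channel,
                window=(int(lo), int(hi)),
                peak_time=p / fs,
                waveform=x[lo:hi].copy(),
                fs=fs,
            )
        )
    return out


def _fourier_shift(w: np.ndarray, delta: float) -> np.ndarray:
    """Circular band-limited shift of ``w`` by ``delta`` samples (rightward)."""
    n = w.size
    k = np.fft.rfftfreq(n, d=1.0) * n
    spec = np.fft.rfft(w) * np.exp(-2j * np.pi * k * delta / n)
    if n % 2 == 0:
        spec[-1] = spec[-1].real  # keep the Nyquist bin real for a real shift
    return np.fft.irfft(spec, n)


def _subsample_peak(a: np.ndarray) -> float:
    """Peak location of ``|a|`` with parabolic sub-sample interpolation."""
    p = int(np.argmax(np.abs(a)))
    if 0 < p < a.size - 1:
        y0, y1, y2 = np.abs(a[p - 1 : p + 2])
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            return p + 0.5 * (y0 - y2) / denom
    return float(p)


def align_segments(segments: list[ActiveSegment]) -> list[ActiveSegment]:
    """Shift every waveform so its magnitude peak sits at the window center.

    The shift is band-limited (Fourier phase ramp) with sub-sample precision;
    ``peak_time`` is updated accordingly.
    """
    if not segments:
        raise ValueError("no segments to align")
    out = []
    for seg in segments:
        w = seg.waveform
        center = w.size // 2
        loc = _subsample_peak(w)
        shifted = _fourier_shift(w, center - loc)
        out.append(
            ActiveSegment(
                channel=seg.channel,
                window=seg.window,
                peak_time=(seg.window[0] + loc) / seg.fs,
                waveform=shifted,
                fs=seg.fs,
            )
        )
    return out


def optics_order(features: np.ndarray, min_pts: int = 40) -> OpticsOrdering:
    """OPTICS ordering with the neighborhood radius set to infinity.

    Every point is a core point; the core distance is the distance to the
    ``min_pts``-th nearest other point.  The ordering starts at the first
    point (reachability = +inf) and repeatedly emits the unprocessed point
    with the smallest reachability, updating reachabilities as
    ``max(core_dist(current), d(current, ·))``.  Ties break toward the lowest
    original index.  Euclidean metric.
    """
    feats = np.asarray(features, dtype=float)
    if feats.ndim == 1:
        feats = feats[:, None]
    n = feats.shape[0]
    if n < min_pts + 1:
        warnings.warn("fewer points than min_pts + 1; empty OPTICS ordering")
        return OpticsOrdering(
            order=np.empty(0, dtype=int), reachability=np.empty(0), min_pts=min_pts
        )
    sq = np.sum(feats**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (feats @ feats.T)
    np.maximum(d2, 0.0, out=d2)
    dist = np.sqrt(d2)
    core = np.partition(dist, min_pts, axis=1)[:, min_pts]
    reach = np.full(n, np.inf)
    processed = np.zeros(n, dtype=bool)
    order = np.empty(n, dtype=int)
    rd_out = np.empty(n)
    current = 0
    for i in range(n):
        order[i] = current
        rd_out[i] = reach[current] if i > 0 else np.inf
        processed[current] = True
        if i == n - 1:
            break
        cand = np.maximum(core[current], dist[current])
        np.minimum(reach, cand, out=reach)
        masked = np.where(processed, np.inf, reach)
        current = int(np.argmin(masked))
    return OpticsOrdering(order=order, reachability=rd_out, min_pts=min_pts)


def extract_valleys(
    ordering: OpticsOrdering,
    segments: list[ActiveSegment] | None = None,
    theta: float = 0.75,
    min_width: int | None = None,
) -> list[ClusterRepresentative]:
    """Reachability-distance valleys of the OPTICS profile.

    The profile is split recursively at significant internal peaks: within
    an interval the highest RD point is a separator whenever the interval
    floor lies below ``theta`` times that peak.  A leaf interval is a valley
    when it holds at least ``min_width`` points whose minimum RD is below
    ``theta`` times its bounding peak (the +inf entry sentinel bounds the
    first interval).  The representative is the point with the minimum RD
    in the valley.
    """
    n = ordering.order.size
    if n == 0:
        return []
    if min_width is None:
        min_width = ordering.min_pts
    rd = ordering.reachability

    valleys: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        # members of the interval are a+1 .. b-1 (a is its left bounding peak)
        if b - a - 1 < 1:
            continue
        inner = slice(a + 1, b)
        m = a + 1 + int(np.argmax(rd[inner]))
        rest = np.concatenate([rd[a + 1 : m], rd[m + 1 : b]])
        if rest.size and np.min(rest) < theta * rd[m]:
            stack.append((a, m))
            stack.append((m, b))
            continue
        if b - a - 1 >= min_width:
            bound = rd[a]
            right = rd[b] if b < n else -np.inf
            peak = max(bound, right)
            if not np.isfinite(peak) or np.min(rd[inner]) < theta * peak:
                valleys.append((a + 1, b))
    reps = []
    for a, b in sorted(valleys):
        rel = int(np.argmin(rd[a:b]))
        pos = a + rel
        seg_idx = int(ordering.order[pos])
        reps.append(
            ClusterRepresentative(
                segment=segments[seg_idx] if segments is not None else seg_idx,
                valley=(a, b),
                rd_at_rep=float(rd[pos]),
                member_order_idx=np.arange(a, b),
            )
        )
    return reps


def representatives_to_initial_points(
    reps: list[ClusterRepresentative],
    fs_decomp: float,
    dedup_ms: float = 1.0,
    max_points: int | None = None,
) -> list[InitialPoint]:
    """Decimate cluster representatives to decomposition-rate initial points.

    Representatives from all channels are pooled, ordered by increasing RD
    (denser clusters first), and points within ``dedup_ms`` of an already
    kept point are dropped.
    """
    if not reps:
        raise ValueError("no cluster representatives")
    ranked = sorted(enumerate(reps), key=lambda kv: (kv[1].rd_at_rep, kv[0]))
    kept: list[InitialPoint] = []
    kept_times: list[float] = []
    tol = dedup_ms * 1e-3
    for cid, rep in ranked:
        t = rep.segment.peak_time
        if any(abs(t - u) < tol for u in kept_times):
            continue
        kept.append(
            InitialPoint(
                sample_index=int(round(t * fs_decomp)),
                source_channel=rep.segment.channel,
                provenance=cid,
            )
        )
        kept_times.append(t)
        if max_points is not None and len(kept) >= max_points:
            break
    return kept


class InitialPointEstimator(BaseEstimator):
    """Channel-wise template clustering that yields CKC initial points.

    Parameters
    ----------
    K : float
        Detection-threshold multiplier (≈ K × baseline RMS).
    min_pts : int
        OPTICS MinPts for a ``min_pts_ref_s``-second epoch; scaled linearly
        with the epoch duration.
    upsample_hz : float
        Segmentation sampling rate.
    valley_theta : float
        RD-valley acceptance fraction of the local surrounding peak.
    features : {"waveform", "lags"}
        Cluster on aligned waveform samples (default) or on the aligned peak
        times only (the literal "time lags" reading).
    max_points : int or None
        Cap on the number of pooled initial points (densest clusters first).

    Attributes
    ----------
    initial_points_ : list of InitialPoint
    representatives_ : list of ClusterRepresentative
    cluster_proxy_times_ : list of ndarray
        Per cluster, the peak times of the representative and its nearest
        neighbors in the ordering (used for cluster-correctness scoring).
    """

    def __init__(
        self,
        K: float = 4.0,
        min_pts: int = 40,
        min_pts_ref_s: float = 10.0,
        upsample_hz: float = 10000.0,
        valley_theta: float = 0.75,
        win_ms: float = 2.0,
        features: str = "waveform",
        max_points: int | None = None,
        n_proxies: int = 20,
    ):
        self.K = K
        self.min_pts = min_pts
        self.min_pts_ref_s = min_pts_ref_s
        self.upsample_hz = upsample_hz
        self.valley_theta = valley_theta
        self.win_ms = win_ms
        self.features = features
        self.max_points = max_points
        self.n_proxies = n_proxies

    def fit(self, rec: EMGRecording, y=None) -> "InitialPointEstimator":
        up = upsample(rec, self.upsample_hz)
        eff_min_pts = max(4, int(round(self.min_pts * rec.duration_s / self.min_pts_ref_s)))
        self.effective_min_pts_ = eff_min_pts
        reps_all: list[ClusterRepresentative] = []
        proxies: list[np.ndarray] = []
        self.orderings_ = []
        for ch in range(up.n_channels):
            x = up.data[ch]
            thr = detection_threshold(x, self.K)
            segs = detect_active_segments(x, thr, fs=up.fs_hz, win_ms=self.win_ms, channel=ch)
            if len(segs) < eff_min_pts + 1:
                continue
            segs = align_segments(segs)
            if self.features == "lags":
                feats = np.array([[s.peak_time] for s in segs])
            else:
                feats = np.array([s.waveform for s in segs])
            ordering = optics_order(feats, eff_min_pts)
            if ordering.order.size == 0:
                continue
            self.orderings_.append((ch, ordering))
            reps = extract_valleys(ordering, segs, self.valley_theta, eff_min_pts)
            for rep in reps:
                reps_all.append(rep)
                # proxy spikes: representative plus nearest points in the ordering
                pos = rep.member_order_idx
                rd_vals = ordering.reachability[pos]
                best = pos[np.argsort(rd_vals, kind="stable")[: self.n_proxies + 1]]
                times = np.array([segs[ordering.order[p]].peak_time for p in best])
                proxies.append(np.sort(times))
        self.representatives_ = reps_all
        if reps_all:
            self.initial_points_ = representatives_to_initial_points(
                reps_all, rec.fs_hz, max_points=self.max_points
            )
            keep = {p.provenance for p in self.initial_points_}
            self.cluster_proxy_times_ = [p for i, p in enumerate(proxies) if i in keep]
        else:
            warnings.warn("no cluster representatives found")
            self.initial_points_ = []
            self.cluster_proxy_times_ = []
        return self

    def save_reachability(self, path) -> None:
        """Write the per-channel reachability profiles as CSV
        (channel, ordered index, RD) for visual inspection."""
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["channel", "ordered_index", "reachability"])
            for ch, ordering in self.orderings_:
                for i, rd in enumerate(ordering.reachability):
                    w.writerow([ch, i, "" if np.isinf(rd) else f"{rd:.6g}"])
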