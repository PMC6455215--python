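"""Synthetic high-density surface EMG with known motor-unit firing trains.

The generator emulates the statistical structure of a constant-force isometric
contraction recorded with a monopolar electrode grid:

* a motor-unit (MU) pool with uniformly distributed fiber counts, normally
  distributed muscle-fiber conduction velocities and a Fuglevand-style
  exponential recruitment-threshold ladder;
* recruitment and rate coding — every MU whose threshold lies below the
  excitation level discharges at ``8 + 0.3 × (excitation − threshold)`` pulses
  per second (pps), capped at 35 pps, with Gaussian inter-spike intervals;
* a parametric spatio-temporal MUAP surrogate: a biphasic waveform (second
  derivative of a Gaussian) whose duration scales with the inverse conduction
  velocity, propagating along the electrode columns with an inter-row delay of
  ``ied / v``, and whose amplitude decays exponentially with the
  electrode-to-territory distance and scales linearly with the fiber count;
* additive colored Gaussian noise, band-limited to 20–500 Hz, at an exact
  requested SNR.

Deep and small MUs in the pool are rendered but not scored; they play the role
of physiological background noise, which is what makes the decomposition
problem realistic.  Only MUs whose territory center is shallower than
``scoreable_depth_mm`` are targets for the decomposition benchmark.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ElectrodeGrid",
    "MotorUnitModel",
    "MUAPTemplate",
    "GroundTruth",
    "EMGRecording",
    "build_mu_pool",
    "generate_firing_trains",
    "synthesize_muaps",
    "render_emg",
    "add_colored_noise",
    "simulate_recording",
]

#: fiber density of the circular MU territories, fibers per square millimetre
FIBER_DENSITY_MM2 = 20.0
#: recruitment range of the threshold ladder (last / first threshold)
RECRUITMENT_RANGE = 30.0
#: excitation at which the last MU of the pool is recruited, fraction of MVC
LAST_RECRUITMENT = 0.6
#: physiological discharge-rate cap, pulses per second
RATE_CAP_PPS = 35.0
#: refractory floor on inter-spike intervals, seconds
ISI_FLOOR_S = 0.020


@dataclass(frozen=True)
class ElectrodeGrid:
    """Monopolar electrode grid geometry.

    ``rows`` run along the muscle-fiber direction (the propagation axis);
    ``cols`` run transversally.  Channel ``k`` maps to ``(row, col) =
    divmod(k, cols)`` (row-major order).
    """

    rows: int
    cols: int
    ied_mm: float = 5.0
    fs_hz: float = 4096.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.ied_mm <= 0 or self.fs_hz <= 0:
            raise ValueError("ied_mm and fs_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def electrode_xy(self) -> np.ndarray:
        """(n_channels, 2) electrode positions in mm, grid-centered.

        x is the transverse (column) coordinate, y the longitudinal (row,
        fiber-direction) coordinate.
        """
        r, c = np.divmod(np.arange(self.n_channels), self.cols)
        x = (c - (self.cols - 1) / 2.0) * self.ied_mm
        y = (r - (self.rows - 1) / 2.0) * self.ied_mm
        return np.column_stack([x, y])


@dataclass(frozen=True)
class MotorUnitModel:
    """One motor unit of the simulated pool."""

    id: int
    n_fibers: int
    territory_center: tuple[float, float, float]  # (x mm, y mm, depth mm)
    conduction_velocity: float  # m/s
    recruitment_threshold: float  # fraction of MVC in [0, 1)
    waveform_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (24 <= self.n_fibers <= 2048):
            raise ValueError("n_fibers outside [24, 2048]")
        if self.conduction_velocity <= 0:
            raise ValueError("conduction velocity must be positive")
        if self.territory_center[2] <= 0:
            raise ValueError("depth must be positive")

    @property
    def territory_radius_mm(self) -> float:
        return math.sqrt(self.n_fibers / (FIBER_DENSITY_MM2 * math.pi))


@dataclass
class MUAPTemplate:
    """Spatio-temporal MUAP surrogate: ``data`` is channels × lags.

    ``ref_lag`` is the template-alignment reference sample: when the MU fires
    at time ``t``, lag ``ref_lag`` of the template lands on sample
    ``round(t * fs)`` of the recording.  The reference is the global peak of
    the template magnitude, so simulated firing times coincide with the
    dominant surface deflection.
    """

    data: np.ndarray
    ref_lag: int
    fs_hz: float


@dataclass
class GroundTruth:
    """Simulated firings and templates used for scoring and oracle tests."""

    firing_times: dict[int, np.ndarray]  # mu_id -> sorted times (s)
    templates: dict[int, MUAPTemplate]
    excitation: float  # % MVC
    active_mu_ids: list[int]
    scoreable_mu_ids: list[int] = field(default_factory=list)
    rates_pps: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mu_id in self.active_mu_ids:
            t = self.firing_times[mu_id]
            if t.size == 0:
                raise ValueError(f"active MU {mu_id} has no firings")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"firing times of MU {mu_id} not increasing")


@dataclass
class EMGRecording:
    """Multichannel surface EMG: ``data`` is channels × samples."""

    data: np.ndarray
    fs_hz: float
    grid: ElectrodeGrid
    montage: str = "monopolar"  # or "single_differential"

    def __post_init__(self) -> None:
        if self.montage == "monopolar":
            expected = self.grid.n_channels
        elif self.montage == "single_differential":
            expected = (self.grid.rows - 1) * self.grid.cols
        else:
            raise ValueError(f"unknown montage {self.montage!r}")
        if self.data.shape[0] != expected:
            raise ValueError(
                f"{self.montage} montage on a {self.grid.rows}x{self.grid.cols} "
                f"grid requires {expected} channels, got {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy_with(self, **kw) -> "EMGRecording":
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        d.update(kw)
        return EMGRecording(**d)


# ---------------------------------------------------------------------------
# pool construction


def build_mu_pool(
    n_mus: int,
    seed: int,
    *,
    depth_range_mm: tuple[float, float] = (2.0, 14.0),
    x_range_mm: tuple[float, float] = (-12.0, 12.0),
    cv_mean: float = 4.0,
    cv_std: float = 0.3,
    cv_floor: float = 2.5,
) -> list[MotorUnitModel]:
    """Draw a motor-unit pool.

    Fiber counts are uniform over {24..2048} (independent of the recruitment
    threshold, as stated for the reference simulation), conduction velocities
    are Normal(4.0, 0.3) m/s truncated at 2.5 m/s, and recruitment thresholds
    follow the Fuglevand exponential ladder
    ``thr_i = exp(i·ln(30)/n)/30 · 0.6`` over (0, 0.6] of MVC.  Territory
    centers are uniform in the transverse direction and in depth; the
    longitudinal endplate offset and a mild waveform-duration jitter give each
    MU a distinct spatio-temporal signature.
    """
    if n_mus < 1:
        raise ValueError("n_mus must be >= 1")
    rng = np.random.default_rng(seed)
    n_fibers = rng.integers(24, 2049, size=n_mus)
    cv = rng.normal(cv_mean, cv_std, size=n_mus)
    while np.any(cv < cv_floor):  # truncated normal by redraw
        bad = cv < cv_floor
        cv[bad] = rng.normal(cv_mean, cv_std, size=int(bad.sum()))
    x = rng.uniform(*x_range_mm, size=n_mus)
    depth = rng.uniform(*depth_range_mm, size=n_mus)
    y = rng.uniform(-8.0, 8.0, size=n_mus)  # endplate-row offset, mm
    ladder = np.exp(np.arange(1, n_mus + 1) * math.log(RECRUITMENT_RANGE) / n_mus)
    thresholds = ladder / RECRUITMENT_RANGE * LAST_RECRUITMENT
    # threshold order is independent of MU geometry/size
    rng.shuffle(thresholds)
    sigma_jitter = rng.uniform(0.85, 1.15, size=n_mus)
    pool = []
    for i in range(n_mus):
        pool.append(
            MotorUnitModel(
                id=i,
                n_fibers=int(n_fibers[i]),
                territory_center=(float(x[i]), float(y[i]), float(depth[i])),
                conduction_velocity=float(cv[i]),
                recruitment_threshold=float(min(thresholds[i], 0.999)),
                waveform_params={
                    "sigma_scale": float(sigma_jitter[i]),
                    "polarity": 1.0,
                },
            )
        )
    return pool


# ---------------------------------------------------------------------------
# firing trains


def generate_firing_trains(
    pool: list[MotorUnitModel],
    excitation: float,
    duration: float,
    isi_cov: float = 0.14,
    seed: int = 0,
    *,
    scoreable_depth_mm: float = 6.0,
) -> GroundTruth:
    """Recruitment and rate coding for one constant-excitation contraction.

    MUs with ``recruitment_threshold < excitation/100`` are active.  The
    target rate is ``8 + 0.3 × (excitation − 100·threshold)`` pps, capped at
    35 pps.  Inter-spike intervals are Gaussian with the requested
    coefficient of variation; draws below the 20-ms refractory floor are
    rejected and redrawn.
    """
    if not pool:
        raise ValueError("empty MU pool")
    if not (0 < excitation <= 100):
        raise ValueError("excitation must be in (0, 100] % MVC")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (0 <= isi_cov < 0.5):
        raise ValueError("isi_cov must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    firing_times: dict[int, np.ndarray] = {}
    rates: dict[int, float] = {}
    active, scoreable = [], []
    for mu in pool:
        if mu.recruitment_threshold >= excitation / 100.0:
            continue
        rate = 8.0 + 0.3 * (excitation - 100.0 * mu.recruitment_threshold)
        rate = min(rate, RATE_CAP_PPS)
        mean_isi = 1.0 / rate
        sd_isi = isi_cov * mean_isi
        times = []
        t = rng.uniform(0.0, mean_isi)
        while t < duration:
            times.append(t)
            isi = rng.normal(mean_isi, sd_isi)
            while isi < ISI_FLOOR_S:
                isi = rng.normal(mean_isi, sd_isi)
            t += isi
        if not times:
            continue
        active.append(mu.id)
        rates[mu.id] = rate
        firing_times[mu.id] = np.asarray(times)
        if mu.territory_center[2] < scoreable_depth_mm:
            scoreable.append(mu.id)
    return GroundTruth(
        firing_times=firing_times,
        templates={},
        excitation=excitation,
        active_mu_ids=active,
        scoreable_mu_ids=scoreable,
        rates_pps=rates,
    )


# ---------------------------------------------------------------------------
# MUAP surrogate


def _ricker(t: np.ndarray, sigma: float) -> np.ndarray:
    """Second derivative of a Gaussian (biphasic analytic MUAP shape)."""
    u = (t / sigma) ** 2
    return (1.0 - u) * np.exp(-u / 2.0)


def synthesize_muaps(
    pool: list[MotorUnitModel],
    grid: ElectrodeGrid,
    *,
    base_sigma_ms: float = 0.45,
    decay_lambda_mm: float = 4.0,
    row_envelope_mm: float = 18.0,
    gain: float = 1.0 / 1024.0,
) -> dict[int, MUAPTemplate]:
    """Parametric spatio-temporal MUAP templates, one per pool MU.

    For MU ``j`` and electrode ``(r, c)`` the waveform is a biphasic pulse of
    width ``base_sigma_ms × sigma_scale × (4 / v_j)`` delayed by
    ``r · ied / v_j`` (propagation along the rows), scaled by

    * ``n_fibers × gain`` (linear fiber-count scaling),
    * ``exp(−sqrt(dx² + depth²)/λ)`` (volume-conductor attenuation with the
      transverse offset ``dx`` and territory depth), and
    * a Gaussian longitudinal envelope centered at the MU endplate row.
    """
    fs = grid.fs_hz
    xy = grid.electrode_xy()
    templates: dict[int, MUAPTemplate] = {}
    for mu in pool:
        x0, y0, depth = mu.territory_center
        v = mu.conduction_velocity
        sigma_s = base_sigma_ms * 1e-3 * mu.waveform_params.get("sigma_scale", 1.0) * (4.0 / v)
        row_delay_s = grid.ied_mm * 1e-3 / v
        max_delay = (grid.rows - 1) * row_delay_s
        half = 4.0 * sigma_s
        n_lags = int(np.ceil((2 * half + max_delay) * fs)) + 1
        lags_t = np.arange(n_lags) / fs - half  # time of lag l relative to row-0 pulse center
        r_idx = np.arange(grid.n_channels) // grid.cols
        delays = r_idx * row_delay_s
        dx = xy[:, 0] - x0
        dist = np.sqrt(dx**2 + depth**2)
        amp = (
            mu.n_fibers
            * gain
            * np.exp(-dist / decay_lambda_mm)
            * np.exp(-((xy[:, 1] - y0) ** 2) / (2 * row_envelope_mm**2))
            * mu.waveform_params.get("polarity", 1.0)
        )
        data = amp[:, None] * _ricker(lags_t[None, :] - delays[:, None], sigma_s)
        ref_lag = int(np.argmax(np.max(np.abs(data), axis=0)))
        templates[mu.id] = MUAPTemplate(data=data, ref_lag=ref_lag, fs_hz=fs)
    return templates


# ---------------------------------------------------------------------------
# rendering and noise


def render_emg(
    truth: GroundTruth,
    templates: dict[int, MUAPTemplate],
    grid: ElectrodeGrid,
    duration: float,
    fs: float | None = None,
) -> EMGRecording:
    """Convolutive mixing: each channel is the sum over active MUs of the
    MUAP template convolved with the MU's binary firing train (monopolar)."""
    fs = grid.fs_hz if fs is None else fs
    n = int(round(duration * fs))
    out = np.zeros((grid.n_channels, n))
    for mu_id in truth.active_mu_ids:
        times = truth.firing_times[mu_id]
        if times.size and times.max() >= duration:
            raise ValueError(f"MU {mu_id} fires beyond the recording duration")
        tpl = templates[mu_id]
        train = np.zeros(n)
        idx = np.round(times * fs).astype(int)
        np.add.at(train, np.clip(idx, 0, n - 1), 1.0)
        conv = sps.fftconvolve(tpl.data, train[None, :], axes=1)
        # place the reference lag of the template on the firing sample
        seg = conv[:, tpl.ref_lag : tpl.ref_lag + n]
        out[:, : seg.shape[1]] += seg
    return EMGRecording(data=out, fs_hz=fs, grid=grid, montage="monopolar")


def add_colored_noise(
    rec: EMGRecording,
    snr_db: float,
    band: tuple[float, float] = (20.0, 500.0),
    seed: int = 0,
) -> EMGRecording:
    """Add band-limited Gaussian noise at an exact global SNR.

    The noise is white Gaussian filtered to ``band`` with a zero-phase
    second-order Butterworth filter, then scaled so that
    ``10·log10(P_signal / P_noise) == snr_db`` over the whole recording.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    p_signal = float(np.mean(rec.data**2))
    if p_signal == 0.0:
        raise ValueError("clean signal has zero power; SNR undefined")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(rec.data.shape)
    sos = sps.butter(2, band, btype="bandpass", fs=rec.fs_hz, output="sos")
    noise = sps.sosfiltfilt(sos, noise, axis=1)
    p_noise = float(np.mean(noise**2))
    noise *= math.sqrt(p_signal / (p_noise * 10.0 ** (snr_db / 10.0)))
    return rec.copy_with(data=rec.data + noise)


# ---------------------------------------------------------------------------
# convenience: one fully specified condition


def simulate_recording(
    *,
    n_mus: int,
    excitation: float,
    snr_db: float,
    duration: float,
    grid: ElectrodeGrid,
    isi_cov: float = 0.14,
    seed: int = 0,
    scoreable_depth_mm: float = 6.0,
    decay_lambda_mm: float = 4.0,
) -> tuple[EMGRecording, GroundTruth]:
    """Simulate one contraction: pool → firings → MUAPs → mixing → noise.

    Sub-seeds for the pool, the firing trains and the noise are derived from
    ``seed`` so that the whole condition is reproducible from one integer.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    pool = build_mu_pool(n_mus, seeds[0])
    truth = generate_firing_trains(
        pool, excitation, duration, isi_cov, seeds[1], scoreable_depth_mm=scoreable_depth_mm
    )
    templates = synthesize_muaps(pool, grid, decay_lambda_mm=decay_lambda_mm)
    truth.templates = {m: templates[m] for m in truth.active_mu_ids}
    clean = render_emg(truth, templates, grid, duration)
    noisy = add_colored_noise(clean, snr_db, seed=seeds[2])
    return noisy, truth
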