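"""End-to-end orchestration: simulate → preprocess → initialize → decompose
→ post-process → score, plus the synthetic benchmark grid.

The benchmark reproduces, at desk scale, the reference validation design:
a 3-SNR × 3-excitation grid of simulated contractions decomposed by the
guided method (clustered initial points, adaptive soft threshold, EM-Kalman)
and by the plain gradient-CKC comparator (peak-based initial points, no
Kalman, hard threshold), both scored against the simulated firings.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import io as gio
from .gss_core import GSSDecomposer
from .initpoints import InitialPoint, InitialPointEstimator
from .mu_post import deduplicate, exclude_mu, extract_firings, firing_stats
from .preprocess import ConvolutiveSphering, bandpass, make_single_differential
from .simulate import ElectrodeGrid, EMGRecording, GroundTruth, simulate_recording
from .validation import cluster_correct, score_decomposition, sir

__all__ = [
    "SimConfig",
    "BenchmarkSpec",
    "BenchmarkReport",
    "EMGDecomposer",
    "run_decomposition",
    "run_benchmark",
]


@dataclass
class SimConfig:
    """Simulation problem size for one benchmark condition.

    The desk-scale default (5 s, 7 rows × 6 columns, 80-MU pool, ≈12–15
    superficial MUs active at 10% MVC) keeps a full benchmark grid within
    minutes on one CPU; ``full()`` restores the reference geometry (16 s,
    10 rows × 9 columns at 4,096 Hz).
    """

    duration_s: float = 5.0
    rows: int = 7
    cols: int = 6
    ied_mm: float = 5.0
    fs_hz: float = 4096.0
    n_mus: int = 80
    isi_cov: float = 0.14
    scoreable_depth_mm: float = 6.0
    decay_lambda_mm: float = 6.0

    @classmethod
    def full(cls) -> "SimConfig":
        return cls(duration_s=16.0, rows=10, cols=9, n_mus=400)

    def grid(self) -> ElectrodeGrid:
        return ElectrodeGrid(rows=self.rows, cols=self.cols, ied_mm=self.ied_mm, fs_hz=self.fs_hz)

    def simulate(self, excitation: float, snr_db: float, seed: int):
        return simulate_recording(
            n_mus=self.n_mus,
            excitation=excitation,
            snr_db=snr_db,
            duration=self.duration_s,
            grid=self.grid(),
            isi_cov=self.isi_cov,
            seed=seed,
            scoreable_depth_mm=self.scoreable_depth_mm,
            decay_lambda_mm=self.decay_lambda_mm,
        )


class EMGDecomposer(BaseEstimator):
    """Full decomposition chain as one estimator.

    Parameters mirror the stage estimators; ``init_method`` selects the
    guided clustering initialization (``"clusters"``) or the comparator's
    whitened-observation peaks (``"peaks"``).

    Attributes
    ----------
    patterns_ : list of FiringPattern
        Kept (physiologically screened, deduplicated) firing patterns.
    all_patterns_ : list of FiringPattern
        Every decomposed pattern before screening.
    excluded_ : list of (mu_id, reasons)
    iterations_ : list of int
        Gradient/Kalman iterations used per kept pattern.
    cluster_proxy_times_ : list of ndarray
        Per-cluster proxy spike times (clustering initialization only).
    """

    def __init__(
        self,
        montage: str = "single_differential",
        band: tuple[float, float] = (20.0, 500.0),
        R: int = 30,
        init_method: str = "clusters",
        max_init_points: int | None = 30,
        K: float = 4.0,
        min_pts: int = 40,
        valley_theta: float = 0.75,
        use_kalman: bool = True,
        adaptive_alpha: bool = True,
        eta0: float = 0.1,
        eta_tau: float = 20.0,
        max_iters: int = 150,
        min_pnr_db: float = 20.0,
        single_precision: bool = True,
        random_state: int | None = 0,
    ):
        self.montage = montage
        self.band = band
        self.R = R
        self.init_method = init_method
        self.max_init_points = max_init_points
        self.K = K
        self.min_pts = min_pts
        self.valley_theta = valley_theta
        self.use_kalman = use_kalman
        self.adaptive_alpha = adaptive_alpha
        self.eta0 = eta0
        self.eta_tau = eta_tau
        self.max_iters = max_iters
        self.min_pnr_db = min_pnr_db
        self.single_precision = single_precision
        self.random_state = random_state

    # -- initialization ----------------------------------------------------

    def _peak_initial_points(self, X: np.ndarray, fs: float) -> list[InitialPoint]:
        """Largest peaks of the whitened-observation energy."""
        from scipy.signal import find_peaks

        energy = np.sum(X**2, axis=0)
        dist = max(1, int(round(0.005 * fs)))
        peaks, props = find_peaks(energy, distance=dist)
        if peaks.size == 0:
            return []
        order = np.argsort(energy[peaks])[::-1]
        n = self.max_init_points or 50
        return [
            InitialPoint(sample_index=int(peaks[i]), source_channel=-1, provenance=int(i))
            for i in order[:n]
        ]

    def preprocess(self, rec: EMGRecording):
        """Band-pass → montage → extension → whitening (shareable)."""
        filtered = bandpass(rec, *self.band)
        sd = make_single_differential(filtered) if (
            self.montage == "single_differential" and rec.montage == "monopolar"
        ) else filtered
        if self.single_precision:
            sd = sd.copy_with(data=sd.data.astype(np.float32))
        obs = ConvolutiveSphering(R=self.R).fit_transform(sd)
        return sd, obs

    def fit(self, rec: EMGRecording, y=None, *, preprocessed=None) -> "EMGDecomposer":
        t0 = time.perf_counter()
        sd, obs = self.preprocess(rec) if preprocessed is None else preprocessed
        self.recording_ = sd
        self.extended_ = obs

        self.cluster_proxy_times_ = []
        if self.init_method == "clusters":
            ipe = InitialPointEstimator(
                K=self.K,
                min_pts=self.min_pts,
                valley_theta=self.valley_theta,
                max_points=self.max_init_points,
            )
            ipe.fit(sd)
            points = ipe.initial_points_
            self.cluster_proxy_times_ = ipe.cluster_proxy_times_
            self.init_estimator_ = ipe
        elif self.init_method == "peaks":
            points = self._peak_initial_points(obs.X, obs.fs_hz)
        else:
            raise ValueError(f"unknown init_method {self.init_method!r}")
        self.initial_points_ = points

        core = GSSDecomposer(
            use_kalman=self.use_kalman,
            adaptive_alpha=self.adaptive_alpha,
            eta0=self.eta0,
            eta_tau=self.eta_tau,
            max_iters=self.max_iters,
            random_state=self.random_state,
        )
        core.fit(obs, points, source_data=sd.data)
        self.core_ = core
        self.estimates_ = core.estimates_

        patterns = []
        for i, est in enumerate(core.estimates_):
            pat = extract_firings(est, mu_id=i)
            pat.provenance = core.point_ids_[i]
            pat.extras["iterations"] = core.iterations_[i]
            firing_stats(pat)
            patterns.append(pat)
        self.all_patterns_ = patterns

        kept, self.excluded_ = [], []
        self.screen_reasons_ = {}
        for pat in patterns:
            ok, reasons = exclude_mu(pat, min_pnr_db=self.min_pnr_db)
            self.screen_reasons_[pat.mu_id] = reasons
            if ok:
                kept.append(pat)
            else:
                self.excluded_.append((pat.mu_id, reasons))
        self.patterns_ = deduplicate(kept)
        self.iterations_ = [p.extras["iterations"] for p in self.patterns_]
        self.fit_time_s_ = time.perf_counter() - t0
        return self

    def score_against(self, truth: GroundTruth, all_patterns: bool = False, **kw) -> list[dict]:
        """Score kept patterns (default) or every decomposed pattern.

        With ``all_patterns`` each record carries ``kept`` (survived the
        physiological screens and deduplication) and the screening
        ``reasons``, which lets downstream analyses look at MU populations
        without conditioning on a particular screen.
        """
        if not all_patterns:
            return score_decomposition(self.patterns_, truth, **kw)
        kept_ids = {p.mu_id for p in self.patterns_}
        records = score_decomposition(self.all_patterns_, truth, **kw)
        for r in records:
            r["kept"] = r["est_mu"] in kept_ids
            r["screen_reasons"] = list(self.screen_reasons_.get(r["est_mu"], []))
        return records


def run_decomposition(
    signal_dir: str | Path,
    out_dir: str | Path,
    config: dict | None = None,
    seed: int = 0,
) -> dict:
    """Decompose a stored recording and write firings, stats and a report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = gio.load_recording(signal_dir)
    params = dict(config or {})
    params.setdefault("random_state", seed)
    dec = EMGDecomposer(**params)
    dec.fit(rec)
    gio.save_firings(dec.patterns_, out / "firings.tsv")
    stats = pd.DataFrame(
        [
            {
                "mu_id": p.mu_id,
                "n_firings": p.n_firings,
                "pnr_db": p.pnr_db,
                "mdr_hz": p.mdr_hz,
                "cov_isi": p.cov_isi,
                "n_inconsistent": p.n_inconsistent,
                "p_d": p.p_d,
                "iterations": p.extras.get("iterations"),
            }
            for p in dec.patterns_
        ]
    )
    stats.to_csv(out / "stats.csv", index=False)
    report = {
        "n_kept_mus": len(dec.patterns_),
        "n_initial_points": len(dec.initial_points_),
        "n_excluded": len(dec.excluded_),
        "excluded": [{"mu_id": m, "reasons": r} for m, r in dec.excluded_],
        "fit_time_s": dec.fit_time_s_,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


# ---------------------------------------------------------------------------
# benchmark harness


@dataclass
class BenchmarkSpec:
    snr_list: tuple = (10.0, 20.0, 30.0)
    mvc_list: tuple = (10.0, 30.0, 50.0)
    replicates: int = 2
    seed: int = 1
    sim: SimConfig = field(default_factory=SimConfig)
    kalman_compare_snr: float | None = None  # re-run without Kalman at this SNR

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not all(np.isfinite(s) for s in self.snr_list):
            raise ValueError("SNR values must be finite")


@dataclass
class BenchmarkReport:
    conditions: pd.DataFrame  # one row per (snr, mvc)
    per_mu: pd.DataFrame  # one row per scored MU record
    per_signal: pd.DataFrame  # one row per (signal, method)
    overall: dict

    def accuracy_table(self) -> pd.DataFrame:
        cols = [
            "snr_db", "mvc", "n_clusters", "n_clusters_correct",
            "roa", "sensitivity", "precision", "n_identified", "sir",
            "iterations", "roa_gckc", "sensitivity_gckc", "precision_gckc",
            "n_identified_gckc",
        ]
        return self.conditions[[c for c in cols if c in self.conditions]]

    def firing_stats_table(self) -> pd.DataFrame:
        cols = ["snr_db", "mvc", "mdr_est", "mdr_true", "cov_est", "cov_true",
                "mdr_bias", "cov_bias"]
        return self.conditions[[c for c in cols if c in self.conditions]]


def _signal_seed(base: int, snr: float, mvc: float, rep: int) -> int:
    ss = np.random.SeedSequence([base, int(snr * 10), int(mvc * 10), rep])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _decompose_and_score(
    rec, truth, *, init_method, use_kalman, adaptive_alpha, seed, preprocessed=None
):
    dec = EMGDecomposer(
        init_method=init_method,
        use_kalman=use_kalman,
        adaptive_alpha=adaptive_alpha,
        random_state=seed,
    )
    dec.fit(rec, preprocessed=preprocessed)
    records = dec.score_against(truth)
    return dec, records


def run_benchmark(spec: BenchmarkSpec, baseline: bool = True, verbose: bool = False) -> BenchmarkReport:
    """Run the benchmark grid and aggregate per-condition statistics.

    For every (SNR, MVC, replicate) one signal is simulated and decomposed
    with the guided method; with ``baseline`` the gradient-CKC comparator
    runs on the same signal.  If ``spec.kalman_compare_snr`` is set, signals
    at that SNR are decomposed a second time with the Kalman stage disabled
    to measure the iteration ratio.
    """
    rows = []
    mu_rows = []
    signal_rows = []
    for snr in spec.snr_list:
        for mvc in spec.mvc_list:
            cond_records, cond_records_g = [], []
            cond = {
                "snr_db": snr, "mvc": mvc, "n_clusters": 0.0, "n_clusters_correct": 0.0,
                "n_identified": 0.0, "n_identified_gckc": 0.0, "sir": np.nan,
                "iterations": np.nan, "iterations_nokalman": np.nan,
            }
            n_clusters, n_correct, sirs, iters, iters_nk = [], [], [], [], []
            n_ident, n_ident_g = [], []
            failures = 0
            for rep in range(spec.replicates):
                sseed = _signal_seed(spec.seed, snr, mvc, rep)
                try:
                    rec, truth = spec.sim.simulate(mvc, snr, sseed)
                    pre = EMGDecomposer(random_state=sseed).preprocess(rec)
                except Exception as exc:  # pragma: no cover - defensive
                    warnings.warn(f"replicate (snr={snr}, mvc={mvc}, rep={rep}) failed: {exc}")
                    failures += 1
                    continue
                dec, records = _decompose_and_score(
                    rec, truth, init_method="clusters", use_kalman=True,
                    adaptive_alpha=True, seed=sseed, preprocessed=pre,
                )
                for r in records:
                    r.update({"snr_db": snr, "mvc": mvc, "rep": rep, "method": "gss"})
                mu_rows.extend(records)
                cond_records.extend(records)
                n_ident.append(_count_identified(records))
                signal_rows.append(
                    {
                        "snr_db": snr, "mvc": mvc, "rep": rep, "method": "gss",
                        "n_identified": _count_identified(records),
                        "n_kept": len(dec.patterns_),
                        "iterations": float(np.mean(dec.iterations_)) if dec.iterations_ else np.nan,
                    }
                )
                n_clusters.append(len(dec.cluster_proxy_times_))
                n_correct.append(
                    sum(
                        cluster_correct(p, truth)
                        for p in dec.cluster_proxy_times_
                        if len(p)
                    )
                )
                iters.extend(dec.iterations_)
                try:
                    sirs.append(sir(dec.recording_, dec.patterns_).sir_mean)
                except Exception:
                    pass
                if baseline:
                    dec_g, records_g = _decompose_and_score(
                        rec, truth, init_method="peaks", use_kalman=False,
                        adaptive_alpha=False, seed=sseed, preprocessed=pre,
                    )
                    for r in records_g:
                        r.update({"snr_db": snr, "mvc": mvc, "rep": rep, "method": "gckc"})
                    mu_rows.extend(records_g)
                    cond_records_g.extend(records_g)
                    n_ident_g.append(_count_identified(records_g))
                    signal_rows.append(
                        {
                            "snr_db": snr, "mvc": mvc, "rep": rep, "method": "gckc",
                            "n_identified": _count_identified(records_g),
                            "n_kept": len(dec_g.patterns_),
                            "iterations": float(np.mean(dec_g.iterations_))
                            if dec_g.iterations_ else np.nan,
                        }
                    )
                if spec.kalman_compare_snr is not None and snr == spec.kalman_compare_snr:
                    dec_nk, _ = _decompose_and_score(
                        rec, truth, init_method="clusters", use_kalman=False,
                        adaptive_alpha=True, seed=sseed, preprocessed=pre,
                    )
                    iters_nk.extend(dec_nk.iterations_)
                    signal_rows.append(
                        {
                            "snr_db": snr, "mvc": mvc, "rep": rep, "method": "gss_nokalman",
                            "n_identified": np.nan,
                            "n_kept": len(dec_nk.patterns_),
                            "iterations": float(np.mean(dec_nk.iterations_))
                            if dec_nk.iterations_ else np.nan,
                        }
                    )
                if verbose:
                    print(
                        f"snr={snr} mvc={mvc} rep={rep}: "
                        f"{_count_identified(records)} identified MUs", flush=True
                    )
            ident = [r for r in cond_records if r["identified"]]
            cond["incomplete"] = failures > 0
            cond.update(_aggregate(ident, ""))
            cond["n_identified"] = float(np.mean(n_ident)) if n_ident else 0.0
            cond["n_clusters"] = float(np.mean(n_clusters)) if n_clusters else 0.0
            cond["n_clusters_correct"] = float(np.mean(n_correct)) if n_correct else 0.0
            cond["sir"] = float(np.mean(sirs)) if sirs else np.nan
            cond["iterations"] = float(np.mean(iters)) if iters else np.nan
            if iters_nk:
                cond["iterations_nokalman"] = float(np.mean(iters_nk))
            if baseline:
                ident_g = [r for r in cond_records_g if r["identified"]]
                cond.update(_aggregate(ident_g, "_gckc"))
                cond["n_identified_gckc"] = float(np.mean(n_ident_g)) if n_ident_g else 0.0
            rows.append(cond)
    conditions = pd.DataFrame(rows)
    per_mu = pd.DataFrame(mu_rows)
    per_signal = pd.DataFrame(signal_rows)
    overall = {}
    if not per_mu.empty:
        gss_ident = per_mu[(per_mu["method"] == "gss") & per_mu["identified"]]
        overall["roa_mean"] = float(gss_ident["roa"].mean())
        overall["n_identified_mean"] = float(conditions["n_identified"].mean())
        if baseline:
            g = per_mu[(per_mu["method"] == "gckc") & per_mu["identified"]]
            overall["roa_gckc_mean"] = float(g["roa"].mean()) if not g.empty else np.nan
            overall["n_identified_gckc_mean"] = float(conditions["n_identified_gckc"].mean())
    return BenchmarkReport(
        conditions=conditions, per_mu=per_mu, per_signal=per_signal, overall=overall
    )


def _count_identified(records: list[dict]) -> int:
    return len({r["true_mu"] for r in records if r["identified"]})


def _aggregate(records: list[dict], suffix: str) -> dict:
    out = {}
    for key in ("roa", "sensitivity", "precision"):
        vals = [r[key] for r in records]
        out[key + suffix] = float(np.mean(vals)) if vals else np.nan
        out[key + "_std" + suffix] = float(np.std(vals)) if vals else np.nan
    if not suffix:
        for key, col in (
            ("mdr_est", "mdr_est_hz"), ("mdr_true", "mdr_true_hz"),
            ("cov_est", "cov_est"), ("cov_true", "cov_true"),
        ):
            vals = [r[col] for r in records if np.isfinite(r[col])]
            out[key] = float(np.mean(vals)) if vals else np.nan
        bias = [abs(r["mdr_bias_hz"]) for r in records if np.isfinite(r["mdr_bias_hz"])]
        out["mdr_bias"] = float(np.mean(bias)) if bias else np.nan
        cbias = [abs(r["cov_bias"]) for r in records if np.isfinite(r["cov_bias"])]
        out["cov_bias"] = float(np.mean(cbias)) if cbias else np.nan
    return out
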