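"""File containers: recordings, firings, templates.

A recording is stored as a directory with ``meta.json`` (sampling rate, grid
geometry, montage, units) and ``signal.f32`` (row-major float32 channels ×
samples).  Firings are a tab-separated file ``mu_id<TAB>firing_time_s``
sorted by time.  Templates go to ``templates.f32`` with a JSON index.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mu_post import FiringPattern
from .simulate import ElectrodeGrid, EMGRecording, MUAPTemplate

__all__ = [
    "save_recording",
    "load_recording",
    "save_firings",
    "load_firings",
    "save_templates",
    "load_templates",
    "export_tsv",
]


def save_recording(rec: EMGRecording, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs_hz": rec.fs_hz,
        "rows": rec.grid.rows,
        "cols": rec.grid.cols,
        "ied_mm": rec.grid.ied_mm,
        "montage": rec.montage,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "units": "a.u.",
        "dtype": "float32",
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    rec.data.astype(np.float32).tofile(path / "signal.f32")


def load_recording(path: str | Path) -> EMGRecording:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    data = np.fromfile(path / "signal.f32", dtype=np.float32).reshape(
        meta["n_channels"], meta["n_samples"]
    )
    grid = ElectrodeGrid(
        rows=meta["rows"], cols=meta["cols"], ied_mm=meta["ied_mm"], fs_hz=meta["fs_hz"]
    )
    return EMGRecording(
        data=data.astype(np.float64), fs_hz=meta["fs_hz"], grid=grid, montage=meta["montage"]
    )


def save_firings(firings: dict[int, np.ndarray] | list[FiringPattern], path: str | Path) -> None:
    """Write ``mu_id<TAB>firing_time_s`` rows sorted by time."""
    if isinstance(firings, list):
        firings = {p.mu_id: p.firing_times for p in firings}
    rows = [
        (mu_id, float(t)) for mu_id, times in firings.items() for t in np.asarray(times)
    ]
    rows.sort(key=lambda r: (r[1], r[0]))
    with open(path, "w") as fh:
        fh.write("mu_id\tfiring_time_s\n")
        for mu_id, t in rows:
            fh.write(f"{mu_id}\t{t:.6f}\n")


def load_firings(path: str | Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {
        int(mu): np.sort(g["firing_time_s"].to_numpy(dtype=float))
        for mu, g in df.groupby("mu_id")
    }


def save_templates(templates: dict[int, MUAPTemplate], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    index = {}
    offset = 0
    with open(path / "templates.f32", "wb") as fh:
        for mu_id, tpl in templates.items():
            arr = tpl.data.astype(np.float32)
            arr.tofile(fh)
            index[str(mu_id)] = {
                "offset": offset,
                "shape": list(arr.shape),
                "ref_lag": tpl.ref_lag,
                "fs_hz": tpl.fs_hz,
            }
            offset += arr.size
    (path / "templates.json").write_text(json.dumps(index, indent=2))


def load_templates(path: str | Path) -> dict[int, MUAPTemplate]:
    path = Path(path)
    index = json.loads((path / "templates.json").read_text())
    flat = np.fromfile(path / "templates.f32", dtype=np.float32)
    out = {}
    for mu_id, e in index.items():
        size = int(np.prod(e["shape"]))
        data = flat[e["offset"] : e["offset"] + size].reshape(e["shape"])
        out[int(mu_id)] = MUAPTemplate(
            data=data.astype(np.float64), ref_lag=e["ref_lag"], fs_hz=e["fs_hz"]
        )
    return out


def export_tsv(rec: EMGRecording, path: str | Path) -> None:
    """Plain-text export, one column per channel."""
    pd.DataFrame(rec.data.T).to_csv(path, sep="\t", index=False, float_format="%.6g")
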