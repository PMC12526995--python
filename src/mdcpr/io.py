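"""On-disk formats: array containers with JSON sidecars, CSV tables, PNGs.

Signals and time-frequency maps are stored as ``.npz`` containers of named
arrays with a ``<name>.json`` sidecar carrying scalar metadata; manifests,
per-cycle tables and evaluation tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .radar import RadarConfig
from .synthetic import SlowTimeSignal, record_signal
from .tfr import TimeFrequencyMap


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_signal(path: str | Path, sig: SlowTimeSignal) -> None:
    path = Path(path)
    np.savez(path, samples=sig.samples)
    meta = {
        "kind": "slow_time_signal",
        "prf_hz": sig.prf_hz,
        "wavelength_m": sig.wavelength_m,
        "provenance": sig.provenance,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))


def load_signal(path: str | Path) -> SlowTimeSignal:
    path = Path(path)
    data = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    return SlowTimeSignal(
        samples=data["samples"],
        prf_hz=meta["prf_hz"],
        wavelength_m=meta["wavelength_m"],
        provenance=meta.get("provenance", {}),
    )


def save_map(path: str | Path, tfmap: TimeFrequencyMap) -> None:
    path = Path(path)
    np.savez(
        path,
        power=tfmap.power,
        time_axis_s=tfmap.time_axis_s,
        freq_axis_hz=tfmap.freq_axis_hz,
    )
    meta = {
        "kind": "time_frequency_map",
        "method": tfmap.method,
        "prf_hz": tfmap.prf_hz,
        "window": tfmap.window,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_map(path: str | Path) -> TimeFrequencyMap:
    path = Path(path)
    data = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    return TimeFrequencyMap(
        power=data["power"],
        time_axis_s=data["time_axis_s"],
        freq_axis_hz=data["freq_axis_hz"],
        method=meta["method"],
        prf_hz=meta["prf_hz"],
        window=meta.get("window", {}),
    )


def save_image_png(path: str | Path, image01: np.ndarray) -> None:
    """Store a [0, 1] grayscale image as 8-bit PNG."""
    arr = np.clip(np.asarray(image01) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def write_campaign(
    manifest: pd.DataFrame, config: RadarConfig, out_dir: str | Path
) -> Path:
    """Materialise a campaign: manifest CSV, signal containers, truth CSVs."""
    out = Path(out_dir)
    (out / "signals").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths, truths = [], []
    for _, row in manifest.iterrows():
        sig, trace = record_signal(row, config)
        rel = f"signals/record_{int(row['record']):04d}.npz"
        save_signal(out / rel, sig)
        paths.append(rel)
        t = trace.per_cycle_truth.copy()
        t["record"] = int(row["record"])
        truths.append(t)
    manifest["path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.concat(truths, ignore_index=True).to_csv(out / "truth.csv", index=False)
    return out / "manifest.csv"
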