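"""From campaign manifests to per-cycle datasets.

Builds the tabular dataset the estimators consume: one row per detected
compression cycle with the Doppler-integration depth estimate, the peak
Doppler feature for the regression model, the matched ground-truth depth,
and (optionally) a fixed-size spectrogram crop of the cycle for the CNN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .depth import estimate_depths
from .radar import RadarConfig
from .synthetic import SlowTimeSignal, record_signal
from .tfr import TimeFrequencyMap, spwvd, stft_spectrogram, to_image

#: Duration of a single-cycle spectrogram crop (covers one compression at
#: 90-110 CPM with margin) and the signed Doppler band retained.
CROP_DURATION_S = 0.8
CROP_FREQ_HZ = 400.0


def match_cycles(estimates: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Attach the reference depth of the overlapping true cycle.

    Each estimated cycle [t_start, t_end] is matched to the ground-truth
    cycle with maximal time overlap; unmatched estimates are dropped.
    """
    if estimates.empty or truth.empty:
        return estimates.assign(depth_ref_cm=pd.Series(dtype=float)).iloc[0:0]
    rows = []
    for _, est in estimates.iterrows():
        o_start = np.maximum(truth["start_s"].to_numpy(), est["t_start_s"])
        o_end = np.minimum(truth["end_s"].to_numpy(), est["t_end_s"])
        overlap = o_end - o_start
        k = int(np.argmax(overlap))
        if overlap[k] <= 0:
            continue
        row = est.to_dict()
        row["depth_ref_cm"] = float(truth["depth_cm"].iloc[k])
        rows.append(row)
    return pd.DataFrame(rows)


def cycle_image(
    tfmap: TimeFrequencyMap,
    t_start_s: float,
    t_end_s: float,
    out_size: tuple[int, int] = (64, 64),
    crop_duration_s: float = CROP_DURATION_S,
    crop_freq_hz: float = CROP_FREQ_HZ,
) -> np.ndarray:
    """Fixed-duration, band-limited grayscale crop around one cycle."""
    center = 0.5 * (t_start_s + t_end_s)
    t0, t1 = center - crop_duration_s / 2, center + crop_duration_s / 2
    ti = (tfmap.time_axis_s >= t0) & (tfmap.time_axis_s <= t1)
    fi = np.abs(tfmap.freq_axis_hz) <= crop_freq_hz
    sub = TimeFrequencyMap(
        power=tfmap.power[np.ix_(ti, fi)],
        time_axis_s=tfmap.time_axis_s[ti],
        freq_axis_hz=tfmap.freq_axis_hz[fi],
        method=tfmap.method,
        prf_hz=tfmap.prf_hz,
        window=tfmap.window,
    )
    return to_image(sub, out_size=out_size)


def record_cycles(
    row: pd.Series,
    config: RadarConfig,
    with_images: bool = False,
    image_tfr: str = "stft",
) -> pd.DataFrame:
    """Process one manifest record into per-cycle rows.

    Runs the Doppler-integration pipeline on the record's signal, matches
    cycles to simulator truth and, when requested, attaches a spectrogram
    crop per cycle (``image_tfr``: "stft" or "spwvd").
    """
    signal, trace = record_signal(row, config)
    est = estimate_depths(signal, aspect_angle_deg=row["angle_deg"])
    matched = match_cycles(est, trace.per_cycle_truth)
    if matched.empty:
        return matched
    for col in ("subject", "case"):
        matched[col] = int(row[col])
    for col in ("angle_deg", "rate_cpm"):
        matched[col] = float(row[col])
    matched["target_depth_cm"] = float(row["depth_cm"])
    matched["record"] = int(row["record"])
    if with_images:
        if image_tfr == "stft":
            tfmap = stft_spectrogram(signal, window_length=64, fft_length=512)
        elif image_tfr == "spwvd":
            tfmap = spwvd(signal, 256, 256, fft_length=512, time_hop=8)
        else:
            raise ValueError(f"unknown image_tfr {image_tfr!r}")
        matched["image"] = [
            cycle_image(tfmap, r["t_start_s"], r["t_end_s"])
            for _, r in matched.iterrows()
        ]
    return matched


def campaign_cycles(
    manifest: pd.DataFrame,
    config: RadarConfig,
    with_images: bool = False,
    image_tfr: str = "stft",
) -> pd.DataFrame:
    """Concatenate :func:`record_cycles` over all manifest rows."""
    parts = [
        record_cycles(row, config, with_images=with_images, image_tfr=image_tfr)
        for _, row in manifest.iterrows()
    ]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)
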