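"""Synchronizing EEG epochs with vehicle telemetry and aggregating.

EEG and telemetry share a Unix time base; each index epoch is joined to
the nearest telemetry sample (within a tolerance), positions are mapped
to the nearest centerline point's segment, and indices are averaged per
(participant, segment).  Driver performance features (total lap time,
invalid percentage, per-lap fatigue) also live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .track import TrackSegmentation


def align_eeg_to_telemetry(index_frame: pd.DataFrame, telemetry: pd.DataFrame,
                           tolerance_s: float = 0.5) -> pd.DataFrame:
    """Join each epoch to the nearest-in-time telemetry sample.

    Epochs without a sample within ``tolerance_s`` are dropped; the drop
    count is attached as ``dropped_epochs``.  Raises when the time
    ranges do not overlap at all.
    """
    tel_t = telemetry["timestamp_s"].to_numpy(dtype=float)
    eeg_t = np.asarray(index_frame.index, dtype=float)
    if eeg_t.min() > tel_t.max() or eeg_t.max() < tel_t.min():
        raise ValueError("EEG and telemetry time ranges do not overlap")
    order = np.argsort(tel_t)
    tel_sorted = tel_t[order]
    pos = np.searchsorted(tel_sorted, eeg_t)
    left = np.clip(pos - 1, 0, len(tel_sorted) - 1)
    right = np.clip(pos, 0, len(tel_sorted) - 1)
    use_right = np.abs(tel_sorted[right] - eeg_t) < np.abs(tel_sorted[left] - eeg_t)
    nearest = np.where(use_right, right, left)
    dt = np.abs(tel_sorted[nearest] - eeg_t)
    keep = dt <= tolerance_s
    if not keep.any():
        raise ValueError("no epoch matched telemetry within tolerance")
    matched = index_frame.loc[keep].copy()
    tel_rows = telemetry.iloc[order[nearest[keep]]].reset_index(drop=True)
    for col in telemetry.columns:
        matched[col] = tel_rows[col].to_numpy()
    matched.dropped_epochs = int((~keep).sum())
    return matched


def map_position_to_segment(frame: pd.DataFrame, segmentation: TrackSegmentation,
                            max_offtrack_m: float = 25.0) -> pd.DataFrame:
    """Label each row by the segment of its nearest centerline point.

    Rows farther than ``max_offtrack_m`` from the centerline keep the
    nearest label; when the telemetry stream carries no ``on_track``
    flag of its own, those rows are flagged off-track here.
    """
    if len(segmentation.xy) == 0:
        raise ValueError("empty segmentation")
    xy = frame[["x_m", "y_m"]].to_numpy(dtype=float)
    dist, idx = cKDTree(segmentation.xy).query(xy)
    out = frame.copy()
    out["segment"] = segmentation.segment_labels()[idx]
    out["centerline_dist_m"] = dist
    if "on_track" not in out.columns:
        out["on_track"] = (dist <= max_offtrack_m).astype(int)
    return out


def aggregate_by_segment(matched: pd.DataFrame, index_cols,
                         participant: str | None = None) -> pd.DataFrame:
    """Unweighted mean of each index per (participant, segment).

    Long format: participant, segment, index, mean, n.  Segments with no
    epochs are simply absent.
    """
    if len(matched) == 0:
        raise ValueError("no matched epochs to aggregate")
    df = matched.copy()
    if participant is not None:
        df["participant"] = participant
    if "participant" not in df.columns:
        raise ValueError("need a participant column or argument")
    g = df.groupby(["participant", "segment"], sort=True)
    rows = []
    for (pid, seg), grp in g:
        for col in index_cols:
            rows.append({"participant": pid, "segment": seg, "index": col,
                         "mean": grp[col].mean(), "n": len(grp)})
    return pd.DataFrame(rows)


@dataclass
class PerformanceFeatures:
    participant: str
    total_lap_time_s: float
    invalid_pct: float
    lap_fatigue: pd.Series | None = None   # lap -> mean fatigue, laps 2..L


def compute_performance(telemetry: pd.DataFrame, matched: pd.DataFrame | None = None,
                        participant: str = "", laps_expected: int = 12,
                        ) -> PerformanceFeatures:
    """Total lap time, time-weighted invalid %, per-lap fatigue means.

    Total lap time is last-lap end minus first-lap start; invalid % is
    the time-weighted fraction of the session with the off-track flag
    set; fatigue trend features are the per-lap means of the matched
    Mental Fatigue epochs over laps 2..L (the out-lap is excluded).
    """
    if "lap" not in telemetry.columns:
        raise ValueError("telemetry lacks a lap column")
    t = telemetry["timestamp_s"].to_numpy(dtype=float)
    total = float(t[-1] - t[0])
    if total <= 0:
        raise ValueError("telemetry spans no time")
    dt = np.diff(t, append=t[-1] + np.median(np.diff(t)))
    off = (telemetry["on_track"].to_numpy() == 0)
    invalid_pct = 100.0 * float(dt[off].sum() / dt.sum())

    lap_fatigue = None
    if matched is not None and "mental_fatigue" in matched.columns:
        n_laps = int(matched["lap"].max())
        if n_laps < 2:
            warnings.warn("fewer than 2 laps; lap-trend features unavailable",
                          stacklevel=2)
        else:
            by_lap = matched.groupby("lap")["mental_fatigue"].mean()
            lap_fatigue = by_lap.loc[by_lap.index >= 2]
    return PerformanceFeatures(participant, total, invalid_pct, lap_fatigue)


def performance_frame(features: list[PerformanceFeatures]) -> pd.DataFrame:
    return pd.DataFrame({
        "participant": [f.participant for f in features],
        "lap_time_s": [f.total_lap_time_s for f in features],
        "invalid_pct": [f.invalid_pct for f in features],
    }).set_index("participant")
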