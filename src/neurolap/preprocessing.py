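"""Ingestion and cleaning of wearable-EEG recordings.

The Muse-class headband used here exports *absolute band power* per epoch
for four channels (frontal AF7/AF8, temporal TP9/TP10) and four canonical
bands (delta 1-4 Hz, theta 4-8 Hz, alpha 8-12 Hz, beta 12-30 Hz) in a
Mind-Monitor-style CSV.  This module reads that dialect, removes transient
non-biological spikes by linear interpolation, and can recompute band
powers from raw 256 Hz samples with a sliding-window FFT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

CHANNELS = ("TP9", "AF7", "AF8", "TP10")
FRONTAL_CHANNELS = ("AF7", "AF8")
BANDS = ("delta", "theta", "alpha", "beta")
#: half-open band edges in Hz: [low, high)
BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}


def _mm_column(band: str, channel: str) -> str:
    return f"{band.capitalize()}_{channel}"


class BandPowerSeries:
    """Timestamped epochs x channels x four absolute band powers.

    Parameters
    ----------
    data
        Wide frame indexed by Unix timestamp (seconds, strictly
        increasing) with a (channel, band) column MultiIndex.
    scale
        ``"linear"`` (default) or ``"log10"``.  All index arithmetic
        requires linear powers; use :meth:`to_linear`.
    """

    def __init__(self, data: pd.DataFrame, scale: str = "linear"):
        if scale not in ("linear", "log10"):
            raise ValueError(f"unknown scale tag {scale!r}")
        ts = np.asarray(data.index, dtype=float)
        if len(ts) and np.any(np.diff(ts) <= 0):
            raise ValueError("epoch timestamps must be strictly increasing")
        if scale == "linear" and len(data) and not (data.to_numpy(float) > 0).all():
            raise ValueError("linear-scale band powers must be strictly positive")
        self.data = data
        self.scale = scale

    # -- basic views ---------------------------------------------------
    @property
    def timestamps(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=float)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.data.columns.get_level_values(0).unique())

    @property
    def n_epochs(self) -> int:
        return len(self.data)

    def band(self, channel: str, band: str) -> np.ndarray:
        return self.data[(channel, band)].to_numpy(dtype=float)

    def copy(self) -> "BandPowerSeries":
        return BandPowerSeries(self.data.copy(), self.scale)

    def to_linear(self) -> "BandPowerSeries":
        if self.scale == "linear":
            return self
        return BandPowerSeries(10.0 ** self.data, "linear")

    # -- construction --------------------------------------------------
    @staticmethod
    def from_arrays(timestamps, powers: dict[tuple[str, str], np.ndarray],
                    scale: str = "linear") -> "BandPowerSeries":
        cols = pd.MultiIndex.from_tuples(sorted(powers), names=["channel", "band"])
        df = pd.DataFrame({c: np.asarray(powers[c], dtype=float) for c in cols},
                          index=pd.Index(np.asarray(timestamps, dtype=float),
                                         name="timestamp"))
        return BandPowerSeries(df[cols], scale)

    # -- Mind-Monitor dialect ------------------------------------------
    def to_mind_monitor_csv(self, path) -> None:
        out = pd.DataFrame({"TimeStamp": self.timestamps})
        for b in BANDS:
            for ch in CHANNELS:
                if (ch, b) in self.data.columns:
                    out[_mm_column(b, ch)] = self.data[(ch, b)].to_numpy()
        # full precision: Unix-epoch timestamps need > 10 significant
        # digits to keep sub-second epoch spacing
        out.to_csv(path, index=False)


@dataclass
class RawEEGSeries:
    """Raw EEG samples (microvolts) per channel at a uniform rate."""

    samples: dict[str, np.ndarray]
    rate_hz: float = 256.0
    start_time: float = 0.0

    def __post_init__(self):
        if self.rate_hz <= 2 * BAND_EDGES["beta"][1]:
            raise ValueError("sampling rate must exceed twice the 30 Hz band edge")
        lengths = {len(v) for v in self.samples.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")


@dataclass
class SpikeReport:
    """Which epochs were interpolated, per (channel, band) series."""

    flagged: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    k: float = 5.0

    @property
    def all_indices(self) -> np.ndarray:
        if not self.flagged:
            return np.array([], dtype=int)
        return np.unique(np.concatenate([np.asarray(v, int) for v in self.flagged.values()]))

    @property
    def n_flagged(self) -> int:
        return int(sum(len(v) for v in self.flagged.values()))


def read_mind_monitor_csv(path, log10: bool = False) -> BandPowerSeries:
    """Read a Mind-Monitor-style band-power CSV.

    Rows missing any band value are dropped (the count is attached to the
    result as ``dropped_rows``).  ``log10=True`` de-logs the stored values
    so downstream ratio indices operate on linear power.
    """
    df = pd.read_csv(path)
    if "TimeStamp" not in df.columns:
        raise ValueError("unrecognized header: missing 'TimeStamp' column")
    expected = {_mm_column(b, ch): (ch, b) for b in BANDS for ch in CHANNELS}
    band_cols = [c for c in df.columns if c in expected]
    unknown = [c for c in df.columns
               if c not in expected and c != "TimeStamp" and not c.startswith("RAW_")]
    if unknown:
        raise ValueError(f"unrecognized column {unknown[0]!r} in {path}")
    if not band_cols:
        raise ValueError("no band-power columns found")

    ts_raw = df["TimeStamp"]
    if ts_raw.dtype == object:
        ts = pd.to_datetime(ts_raw).astype("int64").to_numpy() / 1e9
    else:
        ts = ts_raw.to_numpy(dtype=float)

    values = df[band_cols].apply(pd.to_numeric, errors="coerce")
    keep = values.notna().all(axis=1).to_numpy()
    dropped = int((~keep).sum())
    values = values.loc[keep]
    ts = ts[keep]
    if np.any(np.diff(ts) <= 0):
        raise ValueError("non-monotone timestamps in EEG file")

    powers = {expected[c]: values[c].to_numpy(dtype=float) for c in band_cols}
    series = BandPowerSeries.from_arrays(ts, powers,
                                         scale="log10" if log10 else "linear")
    if log10:
        series = series.to_linear()
    series.dropped_rows = dropped
    return series


def select_frontal(series: BandPowerSeries) -> BandPowerSeries:
    """Restrict a series to the frontal channels AF7 and AF8."""
    for ch in FRONTAL_CHANNELS:
        if ch not in series.channels:
            raise ValueError(f"missing frontal channel {ch}")
    cols = [c for c in series.data.columns if c[0] in FRONTAL_CHANNELS]
    return BandPowerSeries(series.data[cols], series.scale)


def _rolling_mad(x: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(x)
    med = s.rolling(window, center=True, min_periods=3).median()
    mad = (s - med).abs().rolling(window, center=True, min_periods=3).median()
    out = mad.to_numpy()
    # floor at the global MAD: a locally quiet stretch must not collapse
    # the threshold below the series' typical variation (and edge epochs
    # with no full window get a defined value)
    global_mad = float(np.median(np.abs(x - np.median(x))))
    out = np.where(np.isfinite(out), np.maximum(out, global_mad), global_mad)
    return out


def _detect_spikes_1d(x: np.ndarray, ts: np.ndarray, window_s: float,
                      k: float, mad_window: int) -> np.ndarray:
    """Flag samples that jump above both flanks within ``window_s``.

    A sample is a spike when it exceeds the last *retained* sample before
    it and the first sample after it by more than ``k`` rolling MADs --
    an immediate rise and fall, the signature of an electrode transient
    rather than a cortical event.  Consecutive flagged samples form runs
    (the "retained" rule lets a run grow while its onset stays the
    reference level).  Strictly positive series (band powers) are
    compared on the log scale, where physiological gain fluctuations are
    additive and the threshold is invariant to the export's units.
    """
    n = len(x)
    if np.all(x > 0):
        x = np.log(x)
    mad = _rolling_mad(x, mad_window)
    flagged = np.zeros(n, dtype=bool)
    last_retained = 0
    for i in range(1, n - 1):
        thr = k * mad[i]
        ok_prev = (ts[i] - ts[last_retained]) <= window_s
        ok_next = (ts[i + 1] - ts[i]) <= window_s
        if (ok_prev and ok_next
                and x[i] - x[last_retained] > thr
                and x[i] - x[i + 1] > thr):
            flagged[i] = True
        else:
            last_retained = i
    return np.flatnonzero(flagged)


def detect_and_interpolate_spikes(series: BandPowerSeries, window_s: float = 1.0,
                                  k: float = 5.0, mad_window: int = 30,
                                  ) -> tuple[BandPowerSeries, SpikeReport]:
    """Remove transient spikes by linear interpolation.

    Operates independently on every (channel, band) series.  Flagged
    samples are replaced by linear interpolation between the nearest
    clean neighbours, so the cleaned series never widens the value range
    of the clean samples.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if series.n_epochs < 3:
        raise ValueError("need at least 3 epochs for spike detection")
    ts = series.timestamps
    cleaned = series.data.copy()
    report = SpikeReport(k=k)
    for col in series.data.columns:
        x = series.data[col].to_numpy(dtype=float)
        idx = _detect_spikes_1d(x, ts, window_s, k, mad_window)
        if len(idx) == len(x):
            raise ValueError(f"all samples flagged as spikes in {col}; signal unusable")
        if len(idx):
            good = np.setdiff1d(np.arange(len(x)), idx)
            x = x.copy()
            x[idx] = np.interp(ts[idx], ts[good], x[good])
            cleaned[col] = x
        report.flagged[col] = idx
    return BandPowerSeries(cleaned, series.scale), report


def compute_band_power_from_raw(raw: RawEEGSeries, window_samples: int = 256,
                                step_samples: int | None = None,
                                taper: str = "hann",
                                notch: bool = True) -> BandPowerSeries:
    """Band powers from raw samples via a sliding-window FFT.

    Each ``window_samples`` window (default 256 samples = 1 s at 256 Hz)
    is mean-detrended, tapered and Fourier-transformed; the periodogram
    is summed over the half-open band ranges.  50 and 60 Hz notch filters
    are applied first (mains interference), mirroring what the headband
    does in hardware.
    """
    fs = raw.rate_hz
    step = window_samples if step_samples is None else step_samples
    if step <= 0 or window_samples <= 0:
        raise ValueError("window and step must be positive")
    n = len(next(iter(raw.samples.values())))
    if window_samples > n:
        raise ValueError("window longer than the recording")
    win = sps.get_window(taper, window_samples)
    scale = 2.0 / (fs * np.sum(win ** 2))
    freqs = np.fft.rfftfreq(window_samples, d=1.0 / fs)
    band_bins = {b: (freqs >= lo) & (freqs < hi) for b, (lo, hi) in BAND_EDGES.items()}

    n_epochs = (n - window_samples) // step + 1
    starts = np.arange(n_epochs) * step
    centers = raw.start_time + (starts + window_samples / 2.0) / fs

    powers: dict[tuple[str, str], np.ndarray] = {}
    for ch, x in raw.samples.items():
        x = np.asarray(x, dtype=float)
        if notch:
            for f0 in (50.0, 60.0):
                b, a = sps.iirnotch(f0, Q=30.0, fs=fs)
                x = sps.filtfilt(b, a, x)
        segs = np.lib.stride_tricks.sliding_window_view(x, window_samples)[::step]
        segs = segs - segs.mean(axis=1, keepdims=True)
        spec = np.abs(np.fft.rfft(segs * win, axis=1)) ** 2 * scale
        for band, mask in band_bins.items():
            p = spec[:, mask].sum(axis=1)
            powers[(ch, band)] = np.maximum(p, np.finfo(float).tiny)
    return BandPowerSeries.from_arrays(centers, powers, scale="linear")
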