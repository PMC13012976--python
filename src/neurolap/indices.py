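"""The eight frontal band-power indices.

All are per-epoch ratios of the frontal (AF7/AF8 channel-mean) absolute
band powers delta, theta, alpha, beta; frontal alpha asymmetry is the
only per-channel quantity, the log-alpha difference AF8 - AF7 (natural
log by default -- the base only rescales it).

=====================  =============================
workload               beta / (alpha + theta)
alertness              beta / alpha
faa                    log(alpha_AF8) - log(alpha_AF7)
arousal_vigilance      beta / theta
relaxation_drowsiness  theta / alpha
consciousness          (alpha + beta) / delta
task_engagement        (theta + alpha) / (alpha + beta)
mental_fatigue         theta / (alpha + beta)
=====================  =============================

Lower task engagement reads as more effortful, active processing;
rising mental fatigue as accumulating cognitive exhaustion; negative
FAA as approach motivation, positive as withdrawal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .preprocessing import BandPowerSeries, FRONTAL_CHANNELS

INDEX_NAMES = ("workload", "alertness", "faa", "arousal_vigilance",
               "relaxation_drowsiness", "consciousness", "task_engagement",
               "mental_fatigue")


def compute_indices(series: BandPowerSeries, faa_log_base: float = np.e,
                    ) -> pd.DataFrame:
    """Eight indices per epoch from frontal band powers.

    Non-FAA indices use the AF7/AF8 mean of each band; all powers must
    be linear-scale and strictly positive.
    """
    if series.scale != "linear":
        raise ValueError("indices require linear-scale powers; call to_linear()")
    for ch in FRONTAL_CHANNELS:
        if ch not in series.channels:
            raise ValueError(f"missing frontal channel {ch}")

    bands = {}
    for b in ("delta", "theta", "alpha", "beta"):
        af7 = series.band("AF7", b)
        af8 = series.band("AF8", b)
        for ch, arr in (("AF7", af7), ("AF8", af8)):
            if np.any(arr <= 0):
                bad = int(np.flatnonzero(arr <= 0)[0])
                raise ValueError(
                    f"nonpositive {b} power at epoch {bad} on channel {ch}")
        bands[b] = 0.5 * (af7 + af8)
    d, th, a, be = bands["delta"], bands["theta"], bands["alpha"], bands["beta"]
    a7 = series.band("AF7", "alpha")
    a8 = series.band("AF8", "alpha")

    out = pd.DataFrame({
        "workload": be / (a + th),
        "alertness": be / a,
        "faa": (np.log(a8) - np.log(a7)) / np.log(faa_log_base),
        "arousal_vigilance": be / th,
        "relaxation_drowsiness": th / a,
        "consciousness": (a + be) / d,
        "task_engagement": (th + a) / (a + be),
        "mental_fatigue": th / (a + be),
    }, index=pd.Index(series.timestamps, name="timestamp"))
    return out


def zscore_per_participant(index_frame: pd.DataFrame, ddof: int = 1,
                           ) -> pd.DataFrame:
    """Within-participant z-scores of each index (sample-SD convention).

    Returns a frame with the raw columns plus ``z_<index>`` columns.
    A constant index gets z = 0 everywhere with a warning.
    """
    if len(index_frame) < 2:
        raise ValueError("z-scoring needs at least 2 epochs")
    out = index_frame.copy()
    for col in index_frame.columns:
        x = index_frame[col].to_numpy(dtype=float)
        sd = x.std(ddof=ddof)
        if sd == 0 or np.ptp(x) == 0:
            warnings.warn(f"index {col!r} is constant; z-scores set to 0",
                          stacklevel=2)
            out[f"z_{col}"] = 0.0
        else:
            out[f"z_{col}"] = (x - x.mean()) / sd
    return out
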