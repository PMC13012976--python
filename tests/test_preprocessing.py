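"""Mind-Monitor ingestion, spike interpolation, FFT band powers."""

import numpy as np
import pandas as pd
import pytest

from neurolap import (BandPowerSeries, RawEEGSeries, compute_band_power_from_raw,
                      detect_and_interpolate_spikes, read_mind_monitor_csv,
                      select_frontal)
from neurolap.preprocessing import BANDS, CHANNELS
from neurolap.synthetic import generate_band_powers, inject_spikes
from neurolap.calibration import default_tiers
from neurolap.synthetic import generate_telemetry, generate_track, seven_turn_plan


def flat_series(n=100, value=1.0, channels=CHANNELS):
    powers = {(ch, b): np.full(n, value) for ch in channels for b in BANDS}
    return BandPowerSeries.from_arrays(np.arange(n, dtype=float), powers)


# -- reader --------------------------------------------------------------

def test_round_trip_through_csv(tmp_path):
    rng = np.random.default_rng(0)
    powers = {(ch, b): rng.uniform(0.1, 10, 50) for ch in CHANNELS for b in BANDS}
    s = BandPowerSeries.from_arrays(1000 + np.arange(50.0), powers)
    s.to_mind_monitor_csv(tmp_path / "eeg.csv")
    back = read_mind_monitor_csv(tmp_path / "eeg.csv")
    pd.testing.assert_frame_equal(back.data, s.data, rtol=1e-9)


def test_incomplete_rows_dropped_and_counted(tmp_path):
    s = flat_series(100)
    path = tmp_path / "eeg.csv"
    s.to_mind_monitor_csv(path)
    df = pd.read_csv(path)
    df.loc[[3, 40, 77], "Alpha_AF7"] = np.nan
    df.to_csv(path, index=False)
    back = read_mind_monitor_csv(path)
    assert back.n_epochs == 97
    assert back.dropped_rows == 3


def test_log10_dialect_delogs(tmp_path):
    powers = {(ch, b): np.full(3, 0.5) for ch in CHANNELS for b in BANDS}
    BandPowerSeries.from_arrays([0.0, 1.0, 2.0], powers, scale="log10"
                                ).to_mind_monitor_csv(tmp_path / "eeg.csv")
    back = read_mind_monitor_csv(tmp_path / "eeg.csv", log10=True)
    assert back.scale == "linear"
    assert back.band("AF7", "alpha")[0] == pytest.approx(10 ** 0.5)


def test_unknown_column_and_non_monotone_rejected(tmp_path):
    s = flat_series(5)
    path = tmp_path / "eeg.csv"
    s.to_mind_monitor_csv(path)
    df = pd.read_csv(path)
    df["Gamma_AF7"] = 1.0
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="Gamma_AF7"):
        read_mind_monitor_csv(path)

    df = df.drop(columns="Gamma_AF7")
    df.loc[3, "TimeStamp"] = 0.0
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="monotone"):
        read_mind_monitor_csv(path)


def test_select_frontal_drops_temporals_and_is_idempotent():
    s = flat_series(10)
    f = select_frontal(s)
    assert set(f.channels) == {"AF7", "AF8"}
    assert f.n_epochs == s.n_epochs
    f2 = select_frontal(f)
    assert set(f2.channels) == {"AF7", "AF8"}
    with pytest.raises(ValueError, match="AF7"):
        select_frontal(flat_series(10, channels=("AF8", "TP9", "TP10")))


# -- spike handling ------------------------------------------------------

def test_single_spike_on_constant_signal_is_replaced():
    s = flat_series(50)
    data = s.data.copy()
    data.iloc[25] *= 50.0
    cleaned, report = detect_and_interpolate_spikes(BandPowerSeries(data))
    assert np.allclose(cleaned.data.to_numpy(), 1.0)
    assert all(25 in set(v) for v in report.flagged.values())


def test_clean_ramp_passes_untouched():
    n = 60
    powers = {(ch, b): np.linspace(1.0, 5.0, n)
              for ch in CHANNELS for b in BANDS}
    s = BandPowerSeries.from_arrays(np.arange(n, dtype=float), powers)
    cleaned, report = detect_and_interpolate_spikes(s)
    assert report.n_flagged == 0
    pd.testing.assert_frame_equal(cleaned.data, s.data)


def test_injected_spikes_recalled_without_false_positives():
    track = generate_track(seven_turn_plan())
    tier = default_tiers()[1]
    tel = generate_telemetry(track, tier, seed=3)
    series, _ = generate_band_powers(tier, tel, track, seed=4)
    n_min = (series.timestamps[-1] - series.timestamps[0]) / 60.0
    corrupted, truth = inject_spikes(series, rate_per_min=100 / n_min,
                                     amplitude_factor=20.0, seed=5)
    assert len(truth) == 100
    cleaned, report = detect_and_interpolate_spikes(corrupted)
    detected = set(report.all_indices)
    assert len(detected & set(truth)) >= 95
    assert len(detected - set(truth)) == 0


def test_interpolation_never_widens_value_range():
    rng = np.random.default_rng(1)
    n = 200
    base = rng.uniform(1.0, 2.0, n)
    powers = {(ch, b): base.copy() for ch in CHANNELS for b in BANDS}
    s = BandPowerSeries.from_arrays(np.arange(n, dtype=float), powers)
    corrupted, truth = inject_spikes(s, rate_per_min=3.0, seed=2)
    cleaned, _ = detect_and_interpolate_spikes(corrupted)
    clean_mask = np.ones(n, dtype=bool)
    clean_mask[truth] = False
    for col in cleaned.data.columns:
        x = cleaned.data[col].to_numpy()
        clean = corrupted.data[col].to_numpy()[clean_mask]
        assert x.min() >= clean.min() - 1e-12
        assert x.max() <= clean.max() + 1e-12


def test_too_few_epochs_rejected():
    s = flat_series(2)
    with pytest.raises(ValueError, match="at least 3"):
        detect_and_interpolate_spikes(s)


# -- FFT band powers -----------------------------------------------------

def sinusoid_raw(freq, amp=10.0, seconds=8, fs=256.0):
    t = np.arange(int(seconds * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return RawEEGSeries({ch: x.copy() for ch in ("AF7", "AF8")}, rate_hz=fs)


def test_pure_alpha_tone_lands_in_alpha_band():
    bp = compute_band_power_from_raw(sinusoid_raw(10.0))
    total = sum(bp.band("AF7", b).sum() for b in BANDS)
    assert bp.band("AF7", "alpha").sum() / total >= 0.95


def test_alpha_power_scales_with_amplitude_squared():
    p1 = compute_band_power_from_raw(sinusoid_raw(10.0, amp=1.0)).band("AF7", "alpha")
    p3 = compute_band_power_from_raw(sinusoid_raw(10.0, amp=3.0)).band("AF7", "alpha")
    assert np.allclose(p3 / p1, 9.0, rtol=1e-6)


def test_beta_tone_dominates_beta_band():
    bp = compute_band_power_from_raw(sinusoid_raw(20.0))
    bands = {b: bp.band("AF8", b).mean() for b in BANDS}
    assert max(bands, key=bands.get) == "beta"


def test_epoch_count_formula():
    raw = sinusoid_raw(10.0, seconds=10)   # N = 2560
    for step in (256, 128, 64):
        bp = compute_band_power_from_raw(raw, step_samples=step)
        assert bp.n_epochs == (2560 - 256) // step + 1


def test_dc_offset_invariance():
    raw = sinusoid_raw(10.0)
    shifted = RawEEGSeries({ch: v + 500.0 for ch, v in raw.samples.items()},
                           rate_hz=raw.rate_hz)
    a = compute_band_power_from_raw(raw).data.to_numpy()
    b = compute_band_power_from_raw(shifted).data.to_numpy()
    assert np.allclose(a, b, rtol=1e-8, atol=1e-12)


def test_white_noise_gain_squared_ratio():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 1, 256 * 40)
    r1 = RawEEGSeries({"AF7": x, "AF8": x}, rate_hz=256.0)
    r2 = RawEEGSeries({"AF7": 2.5 * x, "AF8": 2.5 * x}, rate_hz=256.0)
    p1 = compute_band_power_from_raw(r1, notch=False).data.to_numpy().sum()
    p2 = compute_band_power_from_raw(r2, notch=False).data.to_numpy().sum()
    assert p2 / p1 == pytest.approx(2.5 ** 2, rel=0.01)


def test_mains_notch_attenuates_50hz_tone():
    clean = compute_band_power_from_raw(sinusoid_raw(10.0))
    t = np.arange(int(8 * 256)) / 256.0
    tone = 10.0 * np.sin(2 * np.pi * 50.0 * t)
    noisy = RawEEGSeries({ch: v + tone for ch, v in
                          sinusoid_raw(10.0).samples.items()}, rate_hz=256.0)
    # total 1-30 Hz power barely changes: the 50 Hz tone is filtered out
    a = clean.data.to_numpy().sum()
    b = compute_band_power_from_raw(noisy).data.to_numpy().sum()
    assert b == pytest.approx(a, rel=0.05)
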