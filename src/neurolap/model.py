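"""The end-to-end study object.

:class:`WorkloadStudy` bundles the four data streams of one cohort
(EEG band powers, telemetry, centerline, questionnaire) and ``fit()``
runs the full analysis in order: spike cleaning -> frontal indices ->
track segmentation -> time alignment and per-segment aggregation ->
performance-tier clustering -> tier/pathway ANOVAs with Tukey post-hocs
-> cubic lap-fatigue trend -> subjective scores and correlations.  The
returned :class:`WorkloadStudyResults` carries every intermediate and a
``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as clu
from . import indices as idx
from . import preprocessing as pre
from . import stats as st
from . import sync, track
from .calibration import default_cohort_spec
from .synthetic import CohortSpec, SyntheticCohort, generate_cohort

KEY_INDICES = ("task_engagement", "mental_fatigue", "faa")


@dataclass
class StudyConfig:
    spike_k: float = 5.0
    spike_window_s: float = 1.0
    half_window: int = 8
    t_low: float = track.T_LOW
    t_high: float = track.T_HIGH
    min_run_m: float = 30.0
    merge_gap_m: float = 50.0
    expected_turns: int | None = 7
    align_tolerance_s: float = 0.5
    cluster_k: int = 4
    cluster_seed: int = 0
    cluster_n_init: int = 50
    standardize_features: bool = True
    feel_weights: tuple[float, float] = (0.5, 0.5)
    use_zscores: bool = False       # z-scores exported either way; the
    trend_degree: int = 3           # group statistics use raw means


class WorkloadStudy:
    """A cohort's data streams plus the analysis configuration."""

    def __init__(self, band_powers: dict[str, pre.BandPowerSeries],
                 telemetry: dict[str, pd.DataFrame],
                 centerline_xy: np.ndarray,
                 questionnaire: pd.DataFrame | None = None,
                 config: StudyConfig | None = None):
        if set(band_powers) != set(telemetry):
            raise ValueError("band_powers and telemetry must cover the "
                             "same participants")
        self.band_powers = band_powers
        self.telemetry = telemetry
        self.centerline_xy = np.asarray(centerline_xy, dtype=float)
        self.questionnaire = questionnaire
        self.config = config or StudyConfig()

    # -- constructors --------------------------------------------------
    @classmethod
    def simulate(cls, spec: CohortSpec | None = None, seed: int = 7,
                 config: StudyConfig | None = None,
                 ) -> tuple["WorkloadStudy", SyntheticCohort]:
        """Build a study from a synthetic cohort (default calibration)."""
        if spec is None:
            spec = default_cohort_spec(seed=seed)
        cohort = generate_cohort(spec)
        study = cls(
            band_powers={p.participant: p.band_powers for p in cohort.participants},
            telemetry={p.participant: p.telemetry for p in cohort.participants},
            centerline_xy=cohort.track.xy,
            questionnaire=cohort.questionnaire_frame,
            config=config)
        return study, cohort

    @classmethod
    def from_directory(cls, path, log10: bool = False,
                       config: StudyConfig | None = None) -> "WorkloadStudy":
        """Load the CSV layout written by ``write_fixture_files``."""
        path = Path(path)
        centerline = track.read_centerline_csv(path / "centerline.csv")
        band_powers, telemetry = {}, {}
        for f in sorted(path.glob("eeg_*.csv")):
            pid = f.stem.removeprefix("eeg_")
            band_powers[pid] = pre.read_mind_monitor_csv(f, log10=log10)
            tf = path / f"telemetry_{pid}.csv"
            if not tf.exists():
                raise FileNotFoundError(f"missing telemetry file for {pid}")
            telemetry[pid] = pd.read_csv(tf)
        if not band_powers:
            raise FileNotFoundError(f"no eeg_*.csv files under {path}")
        qf = path / "questionnaire.csv"
        quest = pd.read_csv(qf, index_col=0) if qf.exists() else None
        return cls(band_powers, telemetry, centerline, quest, config)

    # -- the pipeline --------------------------------------------------
    def fit(self) -> "WorkloadStudyResults":
        cfg = self.config
        segmentation = track.segment_track(
            self.centerline_xy, half_window=cfg.half_window,
            t_low=cfg.t_low, t_high=cfg.t_high, min_run_m=cfg.min_run_m,
            merge_gap_m=cfg.merge_gap_m, expected_turns=cfg.expected_turns)

        epoch_frames = []
        spike_reports = {}
        perf_rows = []
        log: dict[str, dict] = {}
        for pid in sorted(self.band_powers):
            series = self.band_powers[pid].to_linear()
            cleaned, report = pre.detect_and_interpolate_spikes(
                series, window_s=cfg.spike_window_s, k=cfg.spike_k)
            spike_reports[pid] = report
            frontal = pre.select_frontal(cleaned)
            index_frame = idx.compute_indices(frontal)
            index_frame = idx.zscore_per_participant(index_frame)
            matched = sync.align_eeg_to_telemetry(
                index_frame, self.telemetry[pid],
                tolerance_s=cfg.align_tolerance_s)
            dropped = matched.dropped_epochs
            matched = sync.map_position_to_segment(matched, segmentation)
            matched.insert(0, "participant", pid)
            epoch_frames.append(matched)
            perf_rows.append(sync.compute_performance(
                self.telemetry[pid], matched, participant=pid))
            log[pid] = {"epochs": len(matched),
                        "dropped_epochs": int(dropped),
                        "spikes_interpolated": report.n_flagged}

        epochs = pd.concat(epoch_frames, ignore_index=True)
        index_cols = [("z_" if cfg.use_zscores else "") + c
                      for c in idx.INDEX_NAMES]
        segment_matrix = sync.aggregate_by_segment(epochs, index_cols)

        features = sync.performance_frame(perf_rows)
        tiers = clu.cluster_performance(
            features, k=cfg.cluster_k, seed=cfg.cluster_seed,
            n_init=cfg.cluster_n_init, standardize=cfg.standardize_features)
        tier3 = tiers.table["tier3"]
        epochs["tier3"] = epochs["participant"].map(tier3)
        seg = segment_matrix.copy()
        seg["tier3"] = seg["participant"].map(tier3)

        # tier comparison: unit = participant x turn means, 3 groups
        turn_rows = seg[seg["segment"].str.startswith("Turn")]
        anova_tables, tukey_tables = {}, {}
        for col in index_cols:
            sub = turn_rows[turn_rows["index"] == col]
            groups = {t: g["mean"].to_numpy() for t, g in sub.groupby("tier3")}
            anova_tables[col] = st.one_way_anova(groups)
            tukey_tables[col] = st.tukey_hsd(groups)

        # pathway comparison within the merged-Potential tier
        pathway_anova = {}
        pot_rows = turn_rows[turn_rows["tier3"] == clu.MERGED_NAME]
        for col in index_cols:
            sub = pot_rows[pot_rows["index"] == col]
            groups = {s: g["mean"].to_numpy() for s, g in sub.groupby("segment")}
            if len(groups) >= 2 and min(len(v) for v in groups.values()) >= 1:
                pathway_anova[col] = st.one_way_anova(groups)

        # lap-wise fatigue trend for the merged-Potential tier, laps 2..L
        fat_col = ("z_" if cfg.use_zscores else "") + "mental_fatigue"
        pot_epochs = epochs[epochs["tier3"] == clu.MERGED_NAME]
        lap_fatigue = pot_epochs.groupby("lap")[fat_col].mean()
        lap_fatigue = lap_fatigue.loc[lap_fatigue.index >= 2]
        trend = None
        if len(lap_fatigue) >= cfg.trend_degree + 2:
            trend = st.fit_polynomial_trend(
                lap_fatigue.index.to_numpy(dtype=float),
                lap_fatigue.to_numpy(), degree=cfg.trend_degree)

        # raw tier-level epoch means (the reported group profiles)
        tier_epoch_means = epochs.groupby("tier3")[list(idx.INDEX_NAMES)].mean()

        subjective = correlations = None
        if self.questionnaire is not None:
            subjective = st.subjective_scores(
                self.questionnaire, weights=cfg.feel_weights)
            overall = epochs.groupby("participant")[list(idx.INDEX_NAMES)].mean()
            correlations = st.correlate_subjective_objective(subjective, overall)

        return WorkloadStudyResults(
            config=cfg, segmentation=segmentation, epochs=epochs,
            segment_matrix=seg, performance=features, tiers=tiers,
            anova_tables=anova_tables, tukey_tables=tukey_tables,
            pathway_anova=pathway_anova, lap_fatigue=lap_fatigue,
            trend=trend, tier_epoch_means=tier_epoch_means,
            subjective=subjective, correlations=correlations,
            spike_reports=spike_reports, stage_log=log)


@dataclass
class WorkloadStudyResults:
    """Everything the pipeline computed, with export helpers."""

    config: StudyConfig
    segmentation: track.TrackSegmentation
    epochs: pd.DataFrame
    segment_matrix: pd.DataFrame
    performance: pd.DataFrame
    tiers: clu.TierAssignment
    anova_tables: dict[str, st.AnovaResult]
    tukey_tables: dict[str, pd.DataFrame]
    pathway_anova: dict[str, st.AnovaResult]
    lap_fatigue: pd.Series
    trend: st.TrendFit | None
    tier_epoch_means: pd.DataFrame
    subjective: pd.DataFrame | None
    correlations: pd.DataFrame | None
    spike_reports: dict = field(default_factory=dict)
    stage_log: dict = field(default_factory=dict)

    # -- convenience queries -------------------------------------------
    def tier_mean(self, index: str, tier: str = "Potential") -> float:
        """Raw epoch-pooled mean of one index over one final tier."""
        return float(self.tier_epoch_means.loc[tier, index])

    def segment_mean(self, index: str, segment: str,
                     tier: str = "Potential") -> float:
        """Epoch-pooled mean of an index in one segment for one tier."""
        sub = self.epochs[(self.epochs["tier3"] == tier)
                          & (self.epochs["segment"] == segment)]
        if len(sub) == 0:
            raise KeyError(f"no epochs for {tier}/{segment}")
        return float(sub[index].mean())

    def summary(self) -> str:
        lines = ["Workload study summary", "=" * 54]
        sizes = self.tiers.table.groupby("tier3").size()
        lines.append("Performance tiers (k-means on lap time / invalid %):")
        for t, n in sizes.items():
            lines.append(f"  {t:<12} n={n}")
        lines.append("")
        lines.append("Tier epoch means (raw indices):")
        lines.append(self.tier_epoch_means.round(4).to_string())
        lines.append("")
        lines.append("Tier ANOVA (unit: participant x turn means):")
        for name, a in self.anova_tables.items():
            lines.append(f"  {name:<22} F({a.df_between},{a.df_within}) = "
                         f"{a.F:7.3f}  p = {a.p:.4g}  eta2 = {a.eta_squared:.3f}")
        if self.trend is not None:
            c = self.trend.coefficients
            lines.append("")
            lines.append("Cubic lap-fatigue trend (merged Potential, laps 2+):")
            lines.append(f"  y = {c[0]:+.4f} x^3 {c[1]:+.4f} x^2 "
                         f"{c[2]:+.4f} x {c[3]:+.4f}")
            lines.append(f"  R^2 = {self.trend.r_squared:.4f}  "
                         f"p = {self.trend.p:.4f}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.segment_matrix.to_csv(out / "segment_index_matrix.csv", index=False)
        self.tiers.table.to_csv(out / "performance_tiers.csv")
        self.segmentation.to_frame().to_csv(out / "track_segmentation.csv",
                                            index=False)
        anova = pd.DataFrame(
            {name: {"F": a.F, "df_between": a.df_between,
                    "df_within": a.df_within, "p": a.p,
                    "eta_squared": a.eta_squared}
             for name, a in self.anova_tables.items()}).T
        anova.to_csv(out / "tier_anova.csv")
        pd.concat({k: v for k, v in self.tukey_tables.items()},
                  names=["index", "row"]).to_csv(out / "tier_tukey.csv")
        if self.correlations is not None:
            self.correlations.to_csv(out / "subjective_correlations.csv",
                                     index=False)
        payload = {
            "tier_epoch_means": {t: row.to_dict() for t, row
                                 in self.tier_epoch_means.iterrows()},
            "stage_log": self.stage_log,
        }
        if self.trend is not None:
            payload["trend"] = {
                "coefficients": list(self.trend.coefficients),
                "r_squared": self.trend.r_squared, "p": self.trend.p}
        with open(out / "summary.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        (out / "summary.txt").write_text(self.summary() + "\n")

    def plot_workload_profile(self, index: str = "task_engagement",
                              tier: str = "Potential", ax=None):
        """Bar chart of one index's mean across the numbered turns."""
        import matplotlib.pyplot as plt
        sub = self.segment_matrix
        sub = sub[(sub["tier3"] == tier) & (sub["index"] == index)
                  & sub["segment"].str.startswith("Turn")]
        means = sub.groupby("segment")["mean"].mean()
        means = means.reindex(sorted(means.index, key=lambda s: int(s[5:])))
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        ax.bar(means.index, means.to_numpy())
        ax.set_ylabel(f"mean {index}")
        ax.set_title(f"{tier} tier workload profile")
        return ax
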