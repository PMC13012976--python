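"""Synthetic cohorts with known ground truth.

The study's raw recordings are not public, so every downstream stage is
exercised against generated data: a closed parametric circuit with seven
numbered corners, constant-speed telemetry whose lap times and off-track
fractions fall in configurable tier ranges, and band-power series built
by *inverting* the ratio indices so that each tier/segment hits target
Task-Engagement / Mental-Fatigue / FAA values exactly (up to optional
jitter).  Because all eight indices are ratios of the four band powers,
one free scale exists per epoch; the generator fixes the gauge
alpha + beta = 1 and applies a shared per-epoch noise factor that leaves
every index bit-unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .preprocessing import BandPowerSeries
from .track import NORMAL_TURN, SHARP_TURN, STRAIGHT, T_HIGH, T_LOW

POSITIVE_EMOTIONS = ("excited", "delighted", "happy", "content", "relaxed", "calm")
NEGATIVE_EMOTIONS = ("tired", "bored", "depressed", "frustrated", "angry", "tense")
EXPERIENCE_ITEMS = ("driving_experience", "car_responsive_feel")


# ---------------------------------------------------------------------------
# track plans
# ---------------------------------------------------------------------------

@dataclass
class TrackElement:
    kind: str                       # "straight" | "arc"
    length_m: float | None = None   # straights
    radius_m: float | None = None   # arcs
    sweep_rad: float | None = None  # arcs; sign = turn direction
    turn_label: int | None = None

    @property
    def arc_length(self) -> float:
        if self.kind == "straight":
            return float(self.length_m)
        return float(self.radius_m * abs(self.sweep_rad))


@dataclass
class TrackPlan:
    elements: list[TrackElement]
    point_spacing_m: float = 5.0

    def __post_init__(self):
        if self.point_spacing_m <= 0:
            raise ValueError("point spacing must be positive")
        if not any(e.kind == "straight" for e in self.elements):
            raise ValueError("plan needs at least one straight element")
        for e in self.elements:
            if e.kind == "arc" and e.radius_m <= 0:
                raise ValueError("arc radii must be positive")


@dataclass
class GeneratedTrack:
    """Uniformly spaced closed centerline plus analytic ground truth."""

    xy: np.ndarray
    arc_length: np.ndarray          # cumulative, arc_length[0] = 0
    true_class: np.ndarray          # straight / normal_turn / sharp_turn
    true_turn: np.ndarray           # 0 = none
    spacing_m: float
    total_length: float

    def true_segment_labels(self) -> np.ndarray:
        lab = np.where(self.true_turn > 0,
                       np.char.add("Turn ", self.true_turn.astype(str)),
                       "Straight")
        return lab.astype(object)

    def write_centerline_csv(self, path) -> None:
        pd.DataFrame({"x_m": self.xy[:, 0], "y_m": self.xy[:, 1]}).to_csv(
            path, index=False, float_format="%.6f")


def _element_point(e: TrackElement, pos, heading, s):
    """Point and heading at arc distance s into element e."""
    if e.kind == "straight":
        d = np.array([np.cos(heading), np.sin(heading)])
        return pos + s * d, heading
    sgn = 1.0 if e.sweep_rad >= 0 else -1.0
    R = e.radius_m
    t = sgn * s / R
    n0 = np.array([-np.sin(heading), np.cos(heading)])
    center = pos + sgn * R * n0
    nt = np.array([-np.sin(heading + t), np.cos(heading + t)])
    return center - sgn * R * nt, heading + t


def generate_track(plan: TrackPlan) -> GeneratedTrack:
    """Sample a plan at uniform arc spacing with per-point ground truth.

    Raises if the element chain does not return to its start within one
    point spacing (reporting the closure gap).
    """
    # walk elements to get entry pose of each and check closure
    pos = np.zeros(2)
    heading = 0.0
    entries = []
    for e in plan.elements:
        entries.append((pos.copy(), heading))
        pos, heading = _element_point(e, pos, heading, e.arc_length)
    gap = float(np.linalg.norm(pos))
    if gap > plan.point_spacing_m:
        raise ValueError(f"track plan does not close: endpoint {gap:.2f} m from start")

    lengths = np.array([e.arc_length for e in plan.elements])
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    total = float(cum[-1])
    n_pts = int(round(total / plan.point_spacing_m))
    spacing = total / n_pts
    s_vals = np.arange(n_pts) * spacing

    # auto-number turning arcs lacking a label
    next_label = 1
    labels = []
    for e in plan.elements:
        if e.kind == "arc" and 1.0 / e.radius_m >= T_LOW:
            if e.turn_label is not None:
                labels.append(e.turn_label)
                next_label = max(next_label, e.turn_label + 1)
            else:
                labels.append(next_label)
                next_label += 1
        else:
            labels.append(0)

    xy = np.empty((n_pts, 2))
    cls = np.empty(n_pts, dtype=object)
    turn = np.zeros(n_pts, dtype=int)
    ei = np.clip(np.searchsorted(cum, s_vals, side="right") - 1,
                 0, len(plan.elements) - 1)
    for i, s in enumerate(s_vals):
        e = plan.elements[ei[i]]
        p0, h0 = entries[ei[i]]
        xy[i], _ = _element_point(e, p0, h0, s - cum[ei[i]])
        if e.kind == "straight":
            cls[i] = STRAIGHT
        else:
            c = 1.0 / e.radius_m
            cls[i] = STRAIGHT if c < T_LOW else (NORMAL_TURN if c < T_HIGH else SHARP_TURN)
            turn[i] = labels[ei[i]]
    return GeneratedTrack(xy=xy, arc_length=s_vals, true_class=cls,
                          true_turn=turn, spacing_m=spacing, total_length=total)


DEFAULT_TURN_RADII = (400.0, 120.0, 100.0, 350.0, 140.0, 450.0, 150.0)


def seven_turn_plan(radii: tuple[float, ...] = DEFAULT_TURN_RADII,
                    circumradius_m: float = 900.0,
                    point_spacing_m: float = 5.0) -> TrackPlan:
    """Closed seven-corner circuit: a regular heptagon with rounded corners.

    Corner radii default to values straddling the 500 m / 167 m radius
    cutoffs so that turns 1, 4 and 6 are normal (wide, high-speed) and
    turns 2, 3, 5 and 7 are sharp (narrow, technical), mirroring a
    Grand-Prix-style mix of corner severities.  The rounded-polygon
    construction closes exactly: each corner arc sweeps the heptagon's
    exterior angle and trims R*tan(angle/2) off its adjacent edges.
    """
    k = len(radii)
    phi = 2 * np.pi / k                         # exterior angle per corner
    side = 2 * circumradius_m * np.sin(np.pi / k)
    trims = [r * np.tan(phi / 2) for r in radii]
    for i in range(k):
        if trims[i] + trims[(i + 1) % k] >= side:
            raise ValueError("corner radii too large for this circumradius")
    elements: list[TrackElement] = [
        TrackElement("straight", length_m=side / 2 - trims[0])]
    for i in range(k):
        elements.append(TrackElement("arc", radius_m=radii[i], sweep_rad=phi,
                                     turn_label=i + 1))
        if i < k - 1:
            elements.append(TrackElement(
                "straight", length_m=side - trims[i] - trims[i + 1]))
    elements.append(TrackElement("straight", length_m=side / 2 - trims[-1]))
    return TrackPlan(elements, point_spacing_m=point_spacing_m)


# ---------------------------------------------------------------------------
# tier profiles
# ---------------------------------------------------------------------------

@dataclass
class SegmentTargets:
    """Target index values driving the band-power inversion."""

    engagement: float
    fatigue: float
    faa: float = 0.0
    consciousness: float = 2.0

    def validate(self, where: str = "") -> None:
        e, f = self.engagement, self.fatigue
        if e <= f:
            raise ValueError(
                f"infeasible targets{where}: engagement ({e}) must exceed "
                f"fatigue ({f}) for alpha = engagement - fatigue to be positive")
        if e - f >= 1:
            raise ValueError(
                f"infeasible targets{where}: engagement - fatigue must be < 1 "
                f"for beta to stay positive")
        if self.consciousness <= 0:
            raise ValueError(f"consciousness target must be positive{where}")


@dataclass
class TierProfile:
    name: str
    n_participants: int
    targets: SegmentTargets
    lap_time_range_s: tuple[float, float]
    invalid_pct_range: tuple[float, float]
    turn_overrides: dict[int, SegmentTargets] = field(default_factory=dict)
    noise_scale: float = 0.3      # shared per-epoch lognormal sigma
    jitter: float = 0.02          # independent per-band lognormal sigma
    positive_mean: float = 5.0
    negative_mean: float = 5.0
    experience_mean: float = 5.0
    responsiveness_mean: float = 5.0
    rating_sd: float = 1.5

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        lo, hi = self.lap_time_range_s
        if not lo <= hi:
            raise ValueError("lap_time_range_s must be a nonempty [low, high]")
        lo, hi = self.invalid_pct_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError("invalid_pct_range must lie within [0, 100]")
        if self.noise_scale < 0 or self.jitter < 0:
            raise ValueError("noise scales must be non-negative")
        self.targets.validate(f" (tier {self.name})")
        for t, tg in self.turn_overrides.items():
            tg.validate(f" (tier {self.name}, turn {t})")

    def targets_for(self, segment_label: str) -> SegmentTargets:
        if segment_label.startswith("Turn "):
            return self.turn_overrides.get(int(segment_label[5:]), self.targets)
        return self.targets


@dataclass
class CohortSpec:
    tiers: list[TierProfile]
    laps: int = 12
    telemetry_rate_hz: float = 10.0
    epoch_rate_hz: float = 1.0
    spike_rate_per_min: float = 0.0
    spike_amplitude: float = 20.0
    seed: int = 0
    plan: TrackPlan | None = None   # default: seven_turn_plan()

    def __post_init__(self):
        if sum(t.n_participants for t in self.tiers) < 1:
            raise ValueError("cohort needs at least one participant")
        if self.laps < 2:
            raise ValueError("lap-trend analysis needs at least 2 laps")


# ---------------------------------------------------------------------------
# telemetry
# ---------------------------------------------------------------------------

def generate_telemetry(track: GeneratedTrack, tier: TierProfile, laps: int = 12,
                       rate_hz: float = 10.0, seed=None,
                       start_time: float = 1_700_000_000.0) -> pd.DataFrame:
    """Constant-speed drive along the centerline.

    The 12-lap total time is drawn uniformly from the tier's lap-time
    range; the off-track flag is set on contiguous excursion blocks whose
    total duration matches a fraction drawn from the tier's invalid-%
    range (to sample rounding).
    """
    if rate_hz <= 0:
        raise ValueError("telemetry rate must be positive")
    if laps < 1:
        raise ValueError("laps must be >= 1")
    from .clustering import uniform_within
    rng = np.random.default_rng(seed)
    total_time = uniform_within(rng, *tier.lap_time_range_s)
    n = int(np.floor(total_time * rate_hz))
    t = np.arange(n) / rate_hz
    L = track.total_length
    v = laps * L / total_time                      # m/s
    dist = v * t
    lap = np.minimum(dist // L, laps - 1).astype(int) + 1
    s_mod = dist % L

    s_knots = np.concatenate([track.arc_length, [L]])
    x_knots = np.concatenate([track.xy[:, 0], track.xy[:1, 0]])
    y_knots = np.concatenate([track.xy[:, 1], track.xy[:1, 1]])
    x = np.interp(s_mod, s_knots, x_knots)
    y = np.interp(s_mod, s_knots, y_knots)

    on_track = np.ones(n, dtype=int)
    invalid_pct = uniform_within(rng, *tier.invalid_pct_range)
    n_off = int(round(invalid_pct / 100.0 * n))
    placed = 0
    attempts = 0
    while placed < n_off and attempts < 10_000:
        attempts += 1
        blk = int(min(n_off - placed, rng.integers(int(5 * rate_hz),
                                                   int(20 * rate_hz) + 1)))
        start = int(rng.integers(0, n - blk + 1))
        if on_track[start:start + blk].all():
            on_track[start:start + blk] = 0
            placed += blk
    if placed < n_off:                             # dense fallback
        free = np.flatnonzero(on_track)[: n_off - placed]
        on_track[free] = 0

    return pd.DataFrame({
        "timestamp_s": start_time + t,
        "x_m": x, "y_m": y,
        "speed_kmh": np.full(n, v * 3.6),
        "lap": lap,
        "on_track": on_track,
    })


# ---------------------------------------------------------------------------
# band powers by index inversion
# ---------------------------------------------------------------------------

#: lag-1 autocorrelation of the shared log-gain drift (~10-epoch memory)
SHARED_NOISE_AR1 = 0.9

def invert_targets(engagement, fatigue, faa, consciousness):
    """Band powers realizing the given index targets, gauge alpha+beta = 1.

    theta = fatigue, alpha = engagement - fatigue, beta = 1 - alpha,
    delta = (alpha+beta)/consciousness; alpha is split across AF8/AF7 as
    2*alpha*g/(1+g), 2*alpha/(1+g) with g = exp(faa) so the channel mean
    stays alpha and log(alpha_AF8) - log(alpha_AF7) = faa exactly.
    """
    e = np.asarray(engagement, float)
    f = np.asarray(fatigue, float)
    if np.any(e <= f):
        raise ValueError("infeasible targets: engagement must exceed fatigue")
    if np.any(e - f >= 1):
        raise ValueError("infeasible targets: engagement - fatigue must be < 1")
    theta = f
    alpha = e - f
    beta = 1.0 - alpha
    delta = 1.0 / np.asarray(consciousness, float)
    g = np.exp(np.asarray(faa, float))
    alpha_af8 = 2.0 * alpha * g / (1.0 + g)
    alpha_af7 = 2.0 * alpha / (1.0 + g)
    return theta, alpha, beta, delta, alpha_af7, alpha_af8


def true_segment_of_positions(track: GeneratedTrack, xy: np.ndarray) -> np.ndarray:
    """Ground-truth segment label of the nearest centerline point."""
    _, idx = cKDTree(track.xy).query(xy)
    return track.true_segment_labels()[idx]


def generate_band_powers(tier: TierProfile, telemetry: pd.DataFrame,
                         track: GeneratedTrack, epoch_rate_hz: float = 1.0,
                         seed=None, jitter: float | None = None,
                         ) -> tuple[BandPowerSeries, np.ndarray]:
    """Per-epoch band powers hitting the tier's per-segment index targets.

    Returns the series and the ground-truth segment label per epoch.
    With ``jitter = 0`` every epoch's engagement/fatigue/FAA equal the
    targets of the segment the car occupies at that instant, exactly;
    the shared per-epoch noise factor never moves any ratio index.
    """
    rng = np.random.default_rng(seed)
    jit = tier.jitter if jitter is None else jitter
    tel_t = telemetry["timestamp_s"].to_numpy()
    n_epochs = int(np.floor((tel_t[-1] - tel_t[0]) * epoch_rate_hz)) + 1
    ts = tel_t[0] + np.arange(n_epochs) / epoch_rate_hz
    near = np.clip(np.searchsorted(tel_t, ts), 0, len(tel_t) - 1)
    labels = true_segment_of_positions(
        track, telemetry[["x_m", "y_m"]].to_numpy()[near])

    uniq = sorted(set(labels))
    tmap = {lab: tier.targets_for(lab) for lab in uniq}
    e = np.array([tmap[l].engagement for l in labels])
    f = np.array([tmap[l].fatigue for l in labels])
    faa = np.array([tmap[l].faa for l in labels])
    c = np.array([tmap[l].consciousness for l in labels])
    theta, alpha, beta, delta, a7, a8 = invert_targets(e, f, faa, c)

    # shared gain: slow AR(1) drift in log power (electrode contact and
    # arousal change over seconds, not epoch to epoch), stationary sigma
    # = tier.noise_scale.  Spikes, by contrast, are single-epoch events.
    rho = SHARED_NOISE_AR1
    z = np.empty(n_epochs)
    eps = rng.normal(0.0, tier.noise_scale, n_epochs)
    z[0] = eps[0]
    for t in range(1, n_epochs):
        z[t] = rho * z[t - 1] + np.sqrt(1.0 - rho ** 2) * eps[t]
    shared = np.exp(z)

    def noisy(base):
        return base * shared * np.exp(rng.normal(0.0, jit, n_epochs))

    powers = {
        ("AF7", "delta"): noisy(delta), ("AF8", "delta"): noisy(delta),
        ("AF7", "theta"): noisy(theta), ("AF8", "theta"): noisy(theta),
        ("AF7", "alpha"): noisy(a7), ("AF8", "alpha"): noisy(a8),
        ("AF7", "beta"): noisy(beta), ("AF8", "beta"): noisy(beta),
    }
    # temporal channels carry the same spectral profile with its own
    # jitter; indices never read them but files must be complete
    for ch in ("TP9", "TP10"):
        for band, base in (("delta", delta), ("theta", theta),
                           ("alpha", alpha), ("beta", beta)):
            powers[(ch, band)] = base * shared * np.exp(
                rng.normal(0.0, max(jit, 0.05), n_epochs))
    return BandPowerSeries.from_arrays(ts, powers), labels


def inject_spikes(series: BandPowerSeries, rate_per_min: float,
                  amplitude_factor: float = 20.0, seed=None,
                  ) -> tuple[BandPowerSeries, np.ndarray]:
    """Multiply isolated epochs by ``amplitude_factor`` in every series.

    Returns the corrupted series and the injected epoch indices (the
    detector's ground truth).  Spike epochs are kept at least two epochs
    apart so each retains clean flanks.
    """
    if rate_per_min < 0:
        raise ValueError("spike rate must be non-negative")
    if amplitude_factor <= 1:
        raise ValueError("amplitude_factor must exceed 1")
    n = series.n_epochs
    duration_min = (series.timestamps[-1] - series.timestamps[0]) / 60.0
    n_spikes = int(round(rate_per_min * duration_min))
    if n_spikes == 0:
        return series.copy(), np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    candidates = np.arange(1, n - 1)
    rng.shuffle(candidates)
    for i in candidates:
        if all(abs(i - j) > 1 for j in chosen):
            chosen.append(int(i))
            if len(chosen) == n_spikes:
                break
    idx = np.array(sorted(chosen), dtype=int)
    data = series.data.copy()
    data.iloc[idx] *= amplitude_factor
    return BandPowerSeries(data, series.scale), idx


# ---------------------------------------------------------------------------
# questionnaire
# ---------------------------------------------------------------------------

def generate_questionnaire(tier: TierProfile, seed=None) -> pd.Series:
    """Integer 0-10 ratings from a truncated, discretized normal."""
    rng = np.random.default_rng(seed)

    def draw(mean):
        return int(np.clip(np.round(rng.normal(mean, tier.rating_sd)), 0, 10))

    out = {emo: draw(tier.positive_mean) for emo in POSITIVE_EMOTIONS}
    out.update({emo: draw(tier.negative_mean) for emo in NEGATIVE_EMOTIONS})
    out["driving_experience"] = draw(tier.experience_mean)
    out["car_responsive_feel"] = draw(tier.responsiveness_mean)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------

@dataclass
class ParticipantRecord:
    participant: str
    tier_true: str
    telemetry: pd.DataFrame
    band_powers: BandPowerSeries
    true_segments: np.ndarray
    questionnaire: pd.Series
    spike_truth: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    track: GeneratedTrack
    participants: list[ParticipantRecord]

    @property
    def questionnaire_frame(self) -> pd.DataFrame:
        return pd.DataFrame({p.participant: p.questionnaire
                             for p in self.participants}).T.rename_axis("participant")


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort from one master seed.

    Per-participant random streams are spawned from the master
    ``SeedSequence``, so individual traces are reproducible even when
    the cohort composition changes.
    """
    plan = spec.plan if spec.plan is not None else seven_turn_plan()
    track = generate_track(plan)
    n_total = sum(t.n_participants for t in spec.tiers)
    streams = np.random.SeedSequence(spec.seed).spawn(n_total)
    participants: list[ParticipantRecord] = []
    i = 0
    for tier in spec.tiers:
        for _ in range(tier.n_participants):
            sub = streams[i].spawn(3)
            pid = f"P{i + 1:02d}"
            telemetry = generate_telemetry(
                track, tier, laps=spec.laps, rate_hz=spec.telemetry_rate_hz,
                seed=sub[0], start_time=1_700_000_000.0 + i * 10_000.0)
            bp, labels = generate_band_powers(
                tier, telemetry, track, epoch_rate_hz=spec.epoch_rate_hz,
                seed=sub[1])
            spike_truth = np.array([], dtype=int)
            if spec.spike_rate_per_min > 0:
                bp, spike_truth = inject_spikes(
                    bp, spec.spike_rate_per_min, spec.spike_amplitude, seed=sub[2])
            quest = generate_questionnaire(tier, seed=sub[2])
            participants.append(ParticipantRecord(
                pid, tier.name, telemetry, bp, labels, quest, spike_truth))
            i += 1
    return SyntheticCohort(spec=spec, track=track, participants=participants)


def write_fixture_files(cohort: SyntheticCohort, outdir) -> dict:
    """Write a cohort as CSV fixtures (Mind-Monitor EEG, telemetry,
    centerline, questionnaire) plus a JSON manifest of the ground truth."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.track.write_centerline_csv(out / "centerline.csv")
    manifest = {"seed": cohort.spec.seed, "participants": {}}
    for p in cohort.participants:
        p.band_powers.to_mind_monitor_csv(out / f"eeg_{p.participant}.csv")
        p.telemetry.to_csv(out / f"telemetry_{p.participant}.csv",
                           index=False, float_format="%.6f")
        manifest["participants"][p.participant] = {
            "tier_true": p.tier_true,
            "n_epochs": int(p.band_powers.n_epochs),
            "spike_epochs": [int(k) for k in p.spike_truth],
        }
    cohort.questionnaire_frame.to_csv(out / "questionnaire.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
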