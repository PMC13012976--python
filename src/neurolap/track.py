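"""Curvature-based segmentation of a closed racing-circuit centerline.

Every centerline point gets a windowed curvature C = Δθ/Δd (heading
change per metre of arc), is classified as straight / normal turn /
sharp turn against two thresholds (0.002 and 0.006 rad/m, i.e. radius
cutoffs of 500 m and ~167 m), and contiguous turn runs are merged and
numbered from the start/finish point with a Normal/Hard difficulty.
Thresholds assume coordinates in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRAIGHT = "straight"
NORMAL_TURN = "normal_turn"
SHARP_TURN = "sharp_turn"

T_LOW = 0.002
T_HIGH = 0.006


@dataclass
class Turn:
    turn_id: int
    point_indices: np.ndarray
    difficulty: str           # "Normal" | "Hard"
    n_sharp: int
    n_normal: int

    @property
    def label(self) -> str:
        return f"Turn {self.turn_id}"


@dataclass
class TrackSegmentation:
    """Per-point curvature/class/turn assignment for a closed centerline."""

    xy: np.ndarray
    curvature: np.ndarray
    point_class: np.ndarray          # str array
    turn_id: np.ndarray              # 0 = not in a turn
    turns: list[Turn] = field(default_factory=list)

    @property
    def n_turns(self) -> int:
        return len(self.turns)

    @property
    def difficulty_map(self) -> dict[int, str]:
        return {t.turn_id: t.difficulty for t in self.turns}

    def segment_labels(self) -> np.ndarray:
        """Human-readable label per point: 'Straight' or 'Turn k'."""
        lab = np.where(self.turn_id > 0,
                       np.char.add("Turn ", self.turn_id.astype(str)),
                       "Straight")
        return lab.astype(object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_m": self.xy[:, 0], "y_m": self.xy[:, 1],
            "curvature": self.curvature, "class": self.point_class,
            "turn_id": self.turn_id,
            "segment": self.segment_labels(),
        })


def _check_centerline(xy: np.ndarray, half_window: int) -> None:
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("centerline must be an (N, 2) array")
    if len(xy) < 2 * half_window + 1:
        raise ValueError("centerline too short for the curvature window")
    seg = np.linalg.norm(np.diff(xy, axis=0, append=xy[:1]), axis=1)
    if np.any(seg[:-1] == 0):
        raise ValueError("duplicate consecutive centerline points")


def compute_curvature(xy: np.ndarray, half_window: int = 8) -> np.ndarray:
    """Windowed unsigned curvature per point of a closed polyline.

    For point i, Δθ is the angle between the chords (i-w -> i) and
    (i -> i+w) and Δd the arc length between the chord midpoints (the
    points i-w/2 and i+w/2), so that C -> 1/R on a circle.
    """
    xy = np.asarray(xy, dtype=float)
    _check_centerline(xy, half_window)
    n = len(xy)
    w = half_window
    idx = np.arange(n)
    before = xy[(idx - w) % n]
    after = xy[(idx + w) % n]
    chord_in = xy - before
    chord_out = after - xy
    cross = chord_in[:, 0] * chord_out[:, 1] - chord_in[:, 1] * chord_out[:, 0]
    dot = (chord_in * chord_out).sum(axis=1)
    dtheta = np.abs(np.arctan2(cross, dot))

    # arc length between the chord midpoints (points at +-w/2)
    seg = np.linalg.norm(xy[(idx + 1) % n] - xy, axis=1)   # seg[i] = |i -> i+1|
    half = w // 2
    cum = np.concatenate([[0.0], np.cumsum(np.tile(seg, 2))])
    start = (idx - half) % n
    dd = cum[start + 2 * half] - cum[start]
    return dtheta / dd


def classify_points(curvature: np.ndarray, t_low: float = T_LOW,
                    t_high: float = T_HIGH) -> np.ndarray:
    """Threshold curvature into straight / normal_turn / sharp_turn.

    Boundaries are lower-inclusive: C < t_low is straight,
    t_low <= C < t_high a normal turn, C >= t_high a sharp turn.
    """
    if t_low >= t_high:
        raise ValueError("t_low must be below t_high")
    c = np.asarray(curvature, dtype=float)
    if np.any(c < 0):
        raise ValueError("curvature must be non-negative")
    out = np.full(len(c), STRAIGHT, dtype=object)
    out[c >= t_low] = NORMAL_TURN
    out[c >= t_high] = SHARP_TURN
    return out


def _circular_runs(mask: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of True in a circular boolean array, as index arrays."""
    n = len(mask)
    if mask.all():
        return [np.arange(n)]
    if not mask.any():
        return []
    # rotate so position 0 is False, then find linear runs
    off = int(np.flatnonzero(~mask)[0])
    rolled = np.roll(mask, -off)
    edges = np.flatnonzero(np.diff(np.concatenate([[False], rolled, [False]]).astype(int)))
    runs = []
    for s, e in zip(edges[::2], edges[1::2]):
        runs.append((np.arange(s, e) + off) % n)
    return runs


def extract_turns(classes: np.ndarray, spacing_m: float,
                  min_run_m: float = 30.0, merge_gap_m: float = 50.0,
                  expected_turns: int | None = None,
                  ) -> tuple[np.ndarray, list[Turn]]:
    """Group non-straight points into numbered turns with difficulty.

    Non-straight runs shorter than ``min_run_m`` are reclassified as
    straight; surviving runs separated by straight gaps shorter than
    ``merge_gap_m`` are merged (an S-complex counts as one turn).  Turns
    are numbered in track order from point 0 (the start/finish line) and
    rated Hard when the majority of their points are sharp, else Normal.
    """
    classes = np.asarray(classes, dtype=object)
    n = len(classes)
    turning = classes != STRAIGHT
    runs = _circular_runs(turning)
    min_pts = max(1, int(round(min_run_m / spacing_m)))
    runs = [r for r in runs if len(r) >= min_pts]

    # merge runs whose circular gap is below merge_gap_m
    gap_pts = int(round(merge_gap_m / spacing_m))
    runs.sort(key=lambda r: r[0])
    merged: list[np.ndarray] = []
    for r in runs:
        if merged:
            gap = (r[0] - merged[-1][-1] - 1) % n
            if gap < gap_pts:
                merged[-1] = np.concatenate([merged[-1], r])
                continue
        merged.append(r)
    if len(merged) > 1:
        wrap_gap = (merged[0][0] - merged[-1][-1] - 1) % n
        if wrap_gap < gap_pts:
            merged[0] = np.concatenate([merged.pop(), merged[0]])

    turn_id = np.zeros(n, dtype=int)
    turns: list[Turn] = []
    for i, r in enumerate(sorted(merged, key=lambda r: r[0]), start=1):
        n_sharp = int(np.sum(classes[r] == SHARP_TURN))
        n_normal = int(np.sum(classes[r] == NORMAL_TURN))
        difficulty = "Hard" if n_sharp > len(r) / 2 else "Normal"
        turn_id[r] = i
        turns.append(Turn(i, r, difficulty, n_sharp, n_normal))
    if expected_turns is not None and len(turns) != expected_turns:
        import warnings
        warnings.warn(f"expected {expected_turns} turns, found {len(turns)}",
                      stacklevel=2)
    return turn_id, turns


def segment_track(xy: np.ndarray, half_window: int = 8,
                  t_low: float = T_LOW, t_high: float = T_HIGH,
                  min_run_m: float = 30.0, merge_gap_m: float = 50.0,
                  expected_turns: int | None = None) -> TrackSegmentation:
    """Full segmentation: curvature -> classes -> numbered turns."""
    xy = np.asarray(xy, dtype=float)
    c = compute_curvature(xy, half_window=half_window)
    classes = classify_points(c, t_low=t_low, t_high=t_high)
    spacing = float(np.median(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
    turn_id, turns = extract_turns(classes, spacing, min_run_m=min_run_m,
                                   merge_gap_m=merge_gap_m,
                                   expected_turns=expected_turns)
    # points dropped by the min-run rule revert to straight in the output
    cleaned = classes.copy()
    cleaned[(turn_id == 0)] = STRAIGHT
    return TrackSegmentation(xy=xy, curvature=c, point_class=cleaned,
                             turn_id=turn_id, turns=turns)


def read_centerline_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("x_m", "y_m"):
        if col not in df.columns:
            raise ValueError(f"centerline CSV missing column {col!r}")
    return df[["x_m", "y_m"]].to_numpy(dtype=float)
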