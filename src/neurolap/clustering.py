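"""Performance-tier stratification by k-means.

Participants are clustered (k = 4 by default) on two features, total
lap time and invalid percentage, z-standardized so seconds and percent
are commensurate.  Clusters are renamed by ascending mean raw lap time
into Most Potential / Potential / Normal / No Potential, and the two
fastest are merged into the final three-tier scheme used for the group
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

TIER4_NAMES = ("MostPotential", "Potential", "Normal", "NoPotential")
MERGED_NAME = "Potential"


@dataclass
class TierAssignment:
    table: pd.DataFrame          # participant-indexed: features, cluster, tier4, tier3
    centroids: pd.DataFrame      # tier4-indexed raw-feature centroids

    def tier_sizes(self, column: str = "tier4") -> pd.Series:
        return self.table[column].value_counts()

    @property
    def merged_potential_size(self) -> int:
        return int((self.table["tier3"] == MERGED_NAME).sum())


def cluster_performance(features: pd.DataFrame, k: int = 4, seed: int = 0,
                        n_init: int = 50, standardize: bool = True,
                        ) -> TierAssignment:
    """k-means on (lap_time_s, invalid_pct) with performance-ordered names.

    Tier names are assigned by ascending mean raw lap time (ties broken
    by lower invalid %), so they never depend on k-means' internal
    cluster ids.  ``tier3`` merges the two fastest tiers.
    """
    required = ("lap_time_s", "invalid_pct")
    for col in required:
        if col not in features.columns:
            raise ValueError(f"features frame missing {col!r}")
    X = features[list(required)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite performance features")
    if len(X) < k:
        raise ValueError(f"need at least {k} participants for k={k}")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("fewer distinct feature rows than clusters")

    Xs = X.copy()
    if standardize:
        sd = Xs.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xs = (Xs - Xs.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Xs)

    lab = km.labels_
    order = sorted(range(k), key=lambda c: (X[lab == c, 0].mean(),
                                            X[lab == c, 1].mean()))
    if k == 4:
        names = {c: TIER4_NAMES[rank] for rank, c in enumerate(order)}
    else:
        names = {c: f"Tier{rank + 1}" for rank, c in enumerate(order)}
    table = features.copy()
    table["cluster"] = lab
    table["tier4"] = [names[c] for c in lab]
    table["tier3"] = merge_tiers(table["tier4"], order_names=[names[c] for c in order])
    centroids = pd.DataFrame(
        [X[lab == c].mean(axis=0) for c in order],
        index=pd.Index([names[c] for c in order], name="tier4"),
        columns=list(required))
    return TierAssignment(table=table, centroids=centroids)


def merge_tiers(tier4: pd.Series, order_names: list[str] | None = None) -> pd.Series:
    """Merge the two fastest tiers into one 'Potential' group.

    Idempotent: labels already in the merged vocabulary pass through.
    """
    if order_names is None:
        # already-merged labels (no MostPotential left) pass through
        if "MostPotential" not in set(tier4):
            return tier4.copy()
        order_names = [n for n in TIER4_NAMES if n in set(tier4)]
    fastest_two = set(order_names[:2])
    return tier4.map(lambda name: MERGED_NAME if name in fastest_two else name)


#: fraction of each performance box's width that draws span, centred.
#: The four boxes overlap each other (the fastest tier's lap-time range
#: encloses the second tier's), so participants are seeded well inside
#: their box rather than uniformly across it -- otherwise the boxes do
#: not define recoverable clusters at all.
RANGE_CONCENTRATION = 0.35


def uniform_within(rng, low: float, high: float,
                   concentration: float = RANGE_CONCENTRATION) -> float:
    """Uniform draw from the central ``concentration`` fraction of a range."""
    c = 0.5 * (low + high)
    h = 0.5 * (high - low) * concentration
    return float(rng.uniform(c - h, c + h))


def draw_performance_boxes(counts=(2, 8, 2, 3),
                           lap_boxes=((1069, 1159), (1121, 1150),
                                      (1226, 1279), (1329, 1395)),
                           invalid_boxes=((4, 18), (34, 88),
                                          (20, 61), (49, 68)),
                           seed: int = 11,
                           concentration: float = RANGE_CONCENTRATION,
                           ) -> pd.DataFrame:
    """Synthetic performance features drawn inside the four tier range
    boxes (lap-time seconds x invalid %), in tier order MostPotential,
    Potential, Normal, NoPotential, concentrated at each box centre."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for (n, lb, ib, name) in zip(counts, lap_boxes, invalid_boxes, TIER4_NAMES):
        for _ in range(n):
            rows.append({"participant": f"P{i + 1:02d}",
                         "lap_time_s": uniform_within(rng, *lb, concentration),
                         "invalid_pct": uniform_within(rng, *ib, concentration),
                         "tier_true": name})
            i += 1
    return pd.DataFrame(rows).set_index("participant")
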