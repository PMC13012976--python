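"""Default study conditions for synthetic cohorts.

The reference cohort mirrors the reported study population: 15 drivers
in four performance tiers (2/8/2/3), a 12-lap ~20-minute session, and
band-power profiles whose Task Engagement, Mental Fatigue and FAA means
match the published tier profiles.  The high-performing tiers
(MostPotential, Potential -- merged into "Potential" for statistics)
additionally carry per-turn engagement/fatigue structure: effortful
engagement peaks (lower values) in the fast Turn 4 and technical
Turn 3, fatigue peaks in the slow Turns 7 and 2.

Values not published (Normal/NoPotential fatigue; three of the seven
per-turn values) are fixed here once, between the published extremes
and respecting the published ordering of the tiers.
"""

from __future__ import annotations

from .synthetic import CohortSpec, SegmentTargets, TierProfile

#: merged-Potential per-turn targets; turns 3, 4, 6, 7 (engagement) and
#: 2, 3, 4, 7 (fatigue) are the published pathway means, the remainder
#: interpolate between the published extremes.
POTENTIAL_TURN_ENGAGEMENT = {1: 0.516, 2: 0.513, 3: 0.509, 4: 0.494,
                             5: 0.511, 6: 0.522, 7: 0.519}
POTENTIAL_TURN_FATIGUE = {1: 0.455, 2: 0.468, 3: 0.460, 4: 0.442,
                          5: 0.463, 6: 0.452, 7: 0.469}


def _potential_overrides() -> dict[int, SegmentTargets]:
    return {t: SegmentTargets(engagement=POTENTIAL_TURN_ENGAGEMENT[t],
                              fatigue=POTENTIAL_TURN_FATIGUE[t],
                              faa=0.488)
            for t in range(1, 8)}


def default_tiers() -> list[TierProfile]:
    potential_base = SegmentTargets(engagement=0.519, fatigue=0.450, faa=0.488)
    return [
        TierProfile(
            name="MostPotential", n_participants=2,
            targets=potential_base, turn_overrides=_potential_overrides(),
            lap_time_range_s=(1069.0, 1159.0), invalid_pct_range=(4.0, 18.0),
            positive_mean=7.5, negative_mean=2.5,
            experience_mean=8.0, responsiveness_mean=7.5),
        TierProfile(
            name="Potential", n_participants=8,
            targets=potential_base, turn_overrides=_potential_overrides(),
            lap_time_range_s=(1121.0, 1150.0), invalid_pct_range=(34.0, 88.0),
            positive_mean=7.0, negative_mean=3.0,
            experience_mean=7.5, responsiveness_mean=7.0),
        TierProfile(
            name="Normal", n_participants=2,
            targets=SegmentTargets(engagement=0.569, fatigue=0.470, faa=0.586),
            lap_time_range_s=(1226.0, 1279.0), invalid_pct_range=(20.0, 61.0),
            positive_mean=5.5, negative_mean=4.5,
            experience_mean=6.0, responsiveness_mean=6.0),
        TierProfile(
            name="NoPotential", n_participants=3,
            targets=SegmentTargets(engagement=0.647, fatigue=0.520, faa=0.506),
            lap_time_range_s=(1329.0, 1395.0), invalid_pct_range=(49.0, 68.0),
            positive_mean=4.0, negative_mean=6.0,
            experience_mean=4.5, responsiveness_mean=5.0),
    ]


def default_cohort_spec(seed: int = 7, **overrides) -> CohortSpec:
    """The reference 15-driver cohort at desk-scale rates.

    Defaults: 12 laps, 10 Hz telemetry, 1 Hz EEG epochs (so each driver
    contributes 1100-1400 epochs over a ~20-minute session).
    """
    kwargs = dict(tiers=default_tiers(), laps=12, telemetry_rate_hz=10.0,
                  epoch_rate_hz=1.0, seed=seed)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)
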