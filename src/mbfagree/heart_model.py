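"""AHA 17-segment left-ventricular model: territories and TAC aggregation.

Segments group into the three coronary vascular territories (LAD, LCx,
RCA); regional and global time-activity curves are weight-normalised
framewise means of member-segment curves, computed BEFORE kinetic
fitting (the global MBF is the fit of the global TAC, not the mean of
segmental MBFs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import TimeActivityCurve

__all__ = ["SegmentScheme", "territory_map", "aggregate_tacs",
           "TERRITORIES", "SEGMENT_IDS"]

SEGMENT_IDS = tuple(range(1, 18))

# AHA-2002 convention; the apex (segment 17) is assigned to LAD.
_DEFAULT_TERRITORY = {
    **{s: "LAD" for s in (1, 2, 7, 8, 13, 14, 17)},
    **{s: "RCA" for s in (3, 4, 9, 10, 15)},
    **{s: "LCx" for s in (5, 6, 11, 12, 16)},
}
TERRITORIES = ("LAD", "LCx", "RCA")


@dataclass(frozen=True)
class SegmentScheme:
    """Segment -> territory mapping plus positive aggregation weights.

    Default weights are equal (1/17); pass relative myocardial volumes
    to weight by segment size instead.
    """

    territory_of: dict = field(default_factory=lambda: dict(_DEFAULT_TERRITORY))
    weight_of: dict = field(default_factory=lambda: {s: 1.0 for s in SEGMENT_IDS})

    def __post_init__(self) -> None:
        if set(self.territory_of) != set(SEGMENT_IDS):
            raise ValueError("territory map must cover segments 1..17 exactly")
        if set(self.weight_of) != set(SEGMENT_IDS):
            raise ValueError("weights must cover segments 1..17 exactly")
        bad = sorted(t for t in set(self.territory_of.values())
                     if t not in TERRITORIES)
        if bad:
            raise ValueError(f"unknown territories: {bad}")
        if any(w <= 0 for w in self.weight_of.values()):
            raise ValueError("segment weights must be positive")

    def segments_in(self, territory: str) -> list[int]:
        if territory not in TERRITORIES:
            raise ValueError(f"unknown territory {territory!r}")
        return sorted(s for s, t in self.territory_of.items() if t == territory)


def territory_map(segment_id: int,
                  scheme: SegmentScheme | None = None) -> str:
    """Vascular territory (LAD/LCx/RCA) of an AHA segment id in 1..17."""
    if segment_id not in SEGMENT_IDS:
        raise ValueError(f"segment id must be in 1..17, got {segment_id}")
    scheme = scheme or SegmentScheme()
    return scheme.territory_of[segment_id]


def aggregate_tacs(segment_tacs: dict, level: str,
                   scheme: SegmentScheme | None = None) -> dict:
    """Weight-normalised framewise mean of segment TACs.

    Parameters
    ----------
    segment_tacs
        Mapping segment id (1..17) -> TimeActivityCurve on one shared
        schedule.
    level
        'global' (one curve keyed 'global') or 'territory' (three curves
        keyed LAD/LCx/RCA).
    """
    scheme = scheme or SegmentScheme()
    missing = sorted(set(SEGMENT_IDS) - set(segment_tacs))
    if missing:
        raise ValueError(f"missing segment TACs: {missing}")
    ref = segment_tacs[1].schedule
    for s in SEGMENT_IDS:
        sch = segment_tacs[s].schedule
        if sch.n_frames != ref.n_frames or not np.allclose(
                sch.frame_start_s, ref.frame_start_s):
            raise ValueError(f"segment {s} TAC is on a different schedule")

    def mean_of(ids) -> np.ndarray:
        w = np.array([scheme.weight_of[s] for s in ids])
        acts = np.stack([segment_tacs[s].activity for s in ids])
        return (w[:, None] * acts).sum(axis=0) / w.sum()

    if level == "global":
        return {"global": TimeActivityCurve(ref, mean_of(SEGMENT_IDS),
                                            region_id="global")}
    if level == "territory":
        return {t: TimeActivityCurve(ref, mean_of(scheme.segments_in(t)),
                                     region_id=t) for t in TERRITORIES}
    raise ValueError(f"level must be 'global' or 'territory', got {level!r}")
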