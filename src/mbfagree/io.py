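"""CSV interchange for TACs, kinetic fits and observer-value tables.

All files are plain UTF-8 CSV with required headers ('.' decimal
separator); any file written by one pipeline stage is re-readable by
the next without loss.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import VALUE_COLUMNS, validate_observer_table
from .kinetics import BLOOD_POOL_REGION, FrameSchedule, TimeActivityCurve

__all__ = ["tacs_to_frame", "frame_to_tacs", "write_tacs", "read_tacs",
           "write_observer_table", "read_observer_table",
           "write_json", "FITS_COLUMNS"]

TAC_COLUMNS = ["subject_id", "region_id", "frame_start_s", "frame_duration_s",
               "activity_kbq_ml"]
FITS_COLUMNS = ["subject_id", "condition", "region_id", "K1", "k2", "tbv",
                "mbf", "wrss", "converged"]


def tacs_to_frame(tacs_by_subject: dict[str, dict[str, TimeActivityCurve]]
                  ) -> pd.DataFrame:
    """Long-format TAC table from {subject: {region: TAC}}."""
    rows = []
    for subject, regions in tacs_by_subject.items():
        for region, tac in regions.items():
            sch = tac.schedule
            for i in range(sch.n_frames):
                rows.append({"subject_id": subject, "region_id": region,
                             "frame_start_s": sch.frame_start_s[i],
                             "frame_duration_s": sch.frame_duration_s[i],
                             "activity_kbq_ml": tac.activity[i]})
    return pd.DataFrame(rows, columns=TAC_COLUMNS)


def frame_to_tacs(df: pd.DataFrame) -> dict[str, dict[str, TimeActivityCurve]]:
    """Rebuild {subject: {region: TAC}} from a long-format TAC table."""
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TAC table lacks columns: {missing}")
    out: dict[str, dict[str, TimeActivityCurve]] = {}
    for (subject, region), grp in df.groupby(["subject_id", "region_id"],
                                             sort=True):
        grp = grp.sort_values("frame_start_s")
        schedule = FrameSchedule(grp["frame_start_s"].to_numpy(),
                                 grp["frame_duration_s"].to_numpy())
        out.setdefault(str(subject), {})[str(region)] = TimeActivityCurve(
            schedule, grp["activity_kbq_ml"].to_numpy(), region_id=str(region),
            is_blood_pool=(str(region) == BLOOD_POOL_REGION))
    return out


def write_tacs(tacs_by_subject: dict, path) -> None:
    tacs_to_frame(tacs_by_subject).to_csv(path, index=False)


def read_tacs(path) -> dict[str, dict[str, TimeActivityCurve]]:
    return frame_to_tacs(pd.read_csv(path))


def write_observer_table(table: pd.DataFrame, path) -> None:
    validate_observer_table(table)[VALUE_COLUMNS].to_csv(path, index=False)


def read_observer_table(path) -> pd.DataFrame:
    return validate_observer_table(pd.read_csv(path))


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
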