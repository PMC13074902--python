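"""Tumor volumetry and exponential growth kinetics.

Two volume estimators are supported, mirroring common preclinical practice:

* caliper-style: three orthogonal diameters (anteroposterior AP, transverse
  TS, craniocaudal CC) with the ellipsoid approximation
  ``V = π/6 · AP · TS · CC``;
* VOI-style: voxel counting over a segmented binary mask.

Growth between two imaging timepoints is summarized by the specific growth
rate ``SGR = 100 · ln(V2/V1) / (t2 − t1)`` in %/day and the volume doubling
time ``DT = ln 2 / (SGR/100)`` in days, assuming exponential growth (the
rate of increase proportional to the current volume).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import VOIMask

__all__ = [
    "CaliperMeasurement",
    "GrowthRecord",
    "ellipsoid_volume",
    "voi_volume",
    "growth_kinetics",
    "kinetics_from_caliper",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CaliperMeasurement:
    """One set of three orthogonal tumor diameters, in mm."""

    subject_id: str
    day: float
    ap: float
    ts: float
    cc: float

    def __post_init__(self) -> None:
        for name in ("ap", "ts", "cc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"diameter {name!r} must be > 0, got {getattr(self, name)}")
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")

    @property
    def volume(self) -> float:
        return ellipsoid_volume(self.ap, self.ts, self.cc)


@dataclass(frozen=True)
class GrowthRecord:
    """Paired volumes and timepoints with derived SGR and doubling time.

    ``sgr`` is in %/day; ``dt`` in days, NaN when the tumor did not grow
    (sgr <= 0), since a doubling time is undefined for non-growing volumes.
    """

    subject_id: str
    v1: float
    v2: float
    t1: float
    t2: float
    sgr: float
    dt: float


def ellipsoid_volume(ap: float, ts: float, cc: float) -> float:
    """Ellipsoid volume π/6·AP·TS·CC from three orthogonal diameters (mm → mm³)."""
    if ap <= 0 or ts <= 0 or cc <= 0:
        raise ValueError(f"all diameters must be > 0, got ap={ap}, ts={ts}, cc={cc}")
    return math.pi / 6.0 * ap * ts * cc


def voi_volume(mask: VOIMask, spacing: tuple[float, float, float] | None = None) -> float:
    """Segmented-volume estimate: in-mask voxel count × voxel volume (mm³)."""
    if spacing is None:
        spacing = mask.spacing
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacings must be > 0, got {spacing}")
    n = mask.n_voxels
    if n == 0:
        raise ValueError("empty mask: no tumor voxels in the VOI")
    return n * float(np.prod(spacing))


def growth_kinetics(
    v1: float, v2: float, t1: float, t2: float, subject_id: str = ""
) -> GrowthRecord:
    """Exponential-growth kinetics between two timepoints.

    Returns SGR in %/day and DT in days.  DT is NaN (flagged non-finite)
    for non-growing tumors; callers exclude those from group statistics.
    """
    if v1 <= 0 or v2 <= 0:
        raise ValueError(f"volumes must be > 0, got v1={v1}, v2={v2}")
    if t2 <= t1:
        raise ValueError(f"timepoints out of order: t2={t2} must exceed t1={t1}")
    sgr = 100.0 * math.log(v2 / v1) / (t2 - t1)
    if sgr > 0:
        dt = math.log(2.0) / (sgr / 100.0)
    else:
        dt = float("nan")
        log.warning(
            "subject %s: non-growing tumor (sgr=%.3f %%/day), doubling time undefined",
            subject_id or "<unknown>",
            sgr,
        )
    return GrowthRecord(subject_id=subject_id, v1=v1, v2=v2, t1=t1, t2=t2, sgr=sgr, dt=dt)


def kinetics_from_caliper(caliper: pd.DataFrame) -> pd.DataFrame:
    """Per-subject growth kinetics from a longitudinal caliper table.

    Expects columns ``subject_id, day, ap_mm, ts_mm, cc_mm`` and optionally
    ``group`` / ``modality``; uses the earliest and latest day per subject
    (and per modality when present).  Returns one row per subject with
    ``v1_mm3, v2_mm3, sgr_pct_per_day, dt_days``.
    """
    required = {"subject_id", "day", "ap_mm", "ts_mm", "cc_mm"}
    missing = required - set(caliper.columns)
    if missing:
        raise ValueError(f"caliper table missing columns: {sorted(missing)}")
    keys = ["subject_id"] + (["modality"] if "modality" in caliper.columns else [])
    rows = []
    for key, sub in caliper.groupby(keys, sort=True):
        sub = sub.sort_values("day")
        if len(sub) < 2:
            raise ValueError(f"subject {key}: need at least two timepoints")
        first, last = sub.iloc[0], sub.iloc[-1]
        v1 = ellipsoid_volume(first.ap_mm, first.ts_mm, first.cc_mm)
        v2 = ellipsoid_volume(last.ap_mm, last.ts_mm, last.cc_mm)
        sid = key[0] if isinstance(key, tuple) else key
        rec = growth_kinetics(v1, v2, float(first.day), float(last.day), subject_id=str(sid))
        row = {
            "subject_id": rec.subject_id,
            "v1_mm3": rec.v1,
            "v2_mm3": rec.v2,
            "t1_day": rec.t1,
            "t2_day": rec.t2,
            "sgr_pct_per_day": rec.sgr,
            "dt_days": rec.dt,
            "method": "caliper",
        }
        if "modality" in caliper.columns:
            row["modality"] = key[1] if isinstance(key, tuple) else None
        if "group" in caliper.columns:
            row["group"] = first.group
        rows.append(row)
    return pd.DataFrame(rows)
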