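"""Binning, timeline anchoring, stage labels and daily extrema.

Days follow the raster convention: a "day" runs from 12:00 noon to 11:59 the
next morning, so the dark (active) phase is contiguous and every day holds
one rest-phase minimum and one active-phase maximum.  Each day is keyed by
the calendar date of its noon start.  Embryonic days (e-days) count from the
estimated copulation date, postnatal days (pn-days) from birth; the birth
day is both e23 and pn0 and is labelled EARLY_POSTNATAL, because the
extended warm phase on the day of birth groups it with the lactation
signature.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import GESTATION_DAYS, IMPLANTATION_E_DAY, WEANING_PN_DAY

__all__ = [
    "StageLabel",
    "ReproductiveTimeline",
    "estimate_copulation_day",
    "timelines_from_metadata",
    "bin_minima",
    "average_across_females",
    "daily_extrema",
    "assign_stage",
    "raster_matrix",
]

BIN_MINUTES_DEFAULT = 20
DAY_SHIFT = pd.Timedelta(hours=12)


class StageLabel(str, enum.Enum):
    NON_PREGNANT = "NON_PREGNANT"
    PRE_IMPLANTATION = "PRE_IMPLANTATION"
    GESTATION = "GESTATION"
    NEAR_BIRTH = "NEAR_BIRTH"
    EARLY_POSTNATAL = "EARLY_POSTNATAL"
    MID_LATE_POSTNATAL = "MID_LATE_POSTNATAL"
    OUT_OF_STUDY = "OUT_OF_STUDY"


#: Stages in physiological order, excluding the out-of-study sentinel.
STAGE_ORDER = [s for s in StageLabel if s is not StageLabel.OUT_OF_STUDY]


@dataclass
class ReproductiveTimeline:
    """Anchor dates for one female (calendar dates of noon-to-noon days)."""

    animal_id: str
    pairing_date: object = None
    birth_date: object = None
    weaning_date: object = None
    copulation_date: object = None  # filled by estimate_copulation_day

    @property
    def anchored(self) -> bool:
        return self.copulation_date is not None

    def e_day(self, day_date) -> int | None:
        if not self.anchored:
            return None
        return (pd.Timestamp(day_date) - pd.Timestamp(self.copulation_date)).days


def estimate_copulation_day(timeline: ReproductiveTimeline) -> ReproductiveTimeline:
    """Anchor a timeline by back-dating the observed birth by 23 days.

    Gestation is treated as a fixed 23 days for a dam that is not
    concurrently lactating.  Without an observed birth date the timeline
    stays unanchored and no stages can be assigned.
    """
    if timeline.birth_date is None or pd.isna(timeline.birth_date):
        timeline.copulation_date = None
        return timeline
    timeline.copulation_date = (
        pd.Timestamp(timeline.birth_date) - pd.Timedelta(days=GESTATION_DAYS)
    ).date()
    return timeline


def timelines_from_metadata(metadata: pd.DataFrame) -> dict[str, ReproductiveTimeline]:
    """Build anchored timelines from a per-animal metadata table."""
    out = {}
    for _, row in metadata.iterrows():
        tl = ReproductiveTimeline(
            animal_id=str(row["animal_id"]),
            pairing_date=row.get("pairing_date"),
            birth_date=row.get("birth_date"),
            weaning_date=row.get("weaning_date"),
        )
        out[tl.animal_id] = estimate_copulation_day(tl)
    return out


def _day_date(timestamps: pd.Series) -> pd.Series:
    """Calendar date of the noon-to-noon day containing each timestamp."""
    return (timestamps - DAY_SHIFT).dt.floor("D").dt.date


def bin_minima(trace: pd.DataFrame, bin_minutes: int = BIN_MINUTES_DEFAULT) -> pd.DataFrame:
    """Minimum retained temperature per clock-aligned bin per animal.

    Bins start on multiples of ``bin_minutes`` from midnight (00:00, 00:20,
    ...).  Bins without reads are simply absent (never zero-filled); the
    raster and averaging steps treat them as missing.  Adds the noon-day
    date and the within-day bin index (bin 0 starts at 12:00).
    """
    if 1440 % bin_minutes:
        raise ValueError("bin_minutes must divide 1440")
    df = trace.copy()
    df["bin_start"] = df["timestamp"].dt.floor(f"{bin_minutes}min")
    out = (df.groupby(["animal_id", "bin_start"], sort=True)["temp_c"]
             .agg(min_c="min", n_reads="size").reset_index())
    out["day_date"] = _day_date(out["bin_start"])
    tod_min = out["bin_start"].dt.hour * 60 + out["bin_start"].dt.minute
    out["bin_index"] = ((tod_min - 720) % 1440) // bin_minutes
    return out


def average_across_females(binned: pd.DataFrame,
                           timelines: dict[str, ReproductiveTimeline]) -> pd.DataFrame:
    """Mean binned minimum per aligned (e-day, bin) across anchored females.

    Each female's bins are re-indexed onto e-days from her own estimated
    copulation date before averaging; the number of contributing females is
    reported per aligned bin.
    """
    anchored = {a: tl for a, tl in timelines.items() if tl.anchored}
    if not anchored:
        raise ValueError("no anchored females to average")
    df = binned[binned["animal_id"].isin(anchored)].copy()
    cop = {a: pd.Timestamp(tl.copulation_date) for a, tl in anchored.items()}
    df["e_day"] = (
        pd.to_datetime(df["day_date"]) - df["animal_id"].map(cop)
    ).dt.days
    return (df.groupby(["e_day", "bin_index"], sort=True)["min_c"]
              .agg(mean_min_c="mean", n_females="size").reset_index())


def assign_stage(e_day: int, pn_day: int | None = None) -> StageLabel:
    """Reproductive-stage label for an anchored day index.

    e0-e5 pre-implantation, e6-e20 gestation, e21-e22 near-birth; the birth
    day (e23 = pn0) opens the early-postnatal stage, which runs through pn8;
    pn9-pn22 is mid-to-late postnatal.  Days before copulation are
    non-pregnant; days past weaning fall out of study.
    """
    if pn_day is None:
        pn_day = e_day - GESTATION_DAYS
    if e_day < 0:
        return StageLabel.NON_PREGNANT
    if e_day < IMPLANTATION_E_DAY:
        return StageLabel.PRE_IMPLANTATION
    if e_day < 21:
        return StageLabel.GESTATION
    if e_day < GESTATION_DAYS:
        return StageLabel.NEAR_BIRTH
    if pn_day <= 8:
        return StageLabel.EARLY_POSTNATAL
    if pn_day <= WEANING_PN_DAY:
        return StageLabel.MID_LATE_POSTNATAL
    return StageLabel.OUT_OF_STUDY


def daily_extrema(trace: pd.DataFrame,
                  timelines: dict[str, ReproductiveTimeline],
                  min_coverage: float = 0.5,
                  bin_minutes: int = BIN_MINUTES_DEFAULT,
                  drop_out_of_study: bool = True) -> pd.DataFrame:
    """Per-animal daily minimum and maximum on the anchored day axis.

    A day must have at least ``min_coverage`` of its 20-minute bins occupied
    to be kept; this guards against dropout-driven fake extrema (e.g. a day
    with reads only in the rest phase has no meaningful maximum).  Days of
    unanchored females are excluded.  Disrupted days (the two days after
    male introduction) are flagged but retained.
    """
    bins_per_day = 1440 // bin_minutes
    df = trace.copy()
    df["day_date"] = _day_date(df["timestamp"])
    df["bin_start"] = df["timestamp"].dt.floor(f"{bin_minutes}min")
    grp = df.groupby(["animal_id", "day_date"], sort=True)
    daily = grp.agg(
        daily_min=("temp_c", "min"),
        daily_max=("temp_c", "max"),
        n_reads=("temp_c", "size"),
        n_bins=("bin_start", "nunique"),
    ).reset_index()
    daily = daily[daily["n_bins"] >= min_coverage * bins_per_day].copy()

    rows = []
    for _, row in daily.iterrows():
        tl = timelines.get(row["animal_id"])
        if tl is None or not tl.anchored:
            continue
        e = tl.e_day(row["day_date"])
        stage = assign_stage(e)
        if drop_out_of_study and stage is StageLabel.OUT_OF_STUDY:
            continue
        disrupted = False
        if tl.pairing_date is not None and not pd.isna(tl.pairing_date):
            dp = (pd.Timestamp(row["day_date"]) - pd.Timestamp(tl.pairing_date)).days
            disrupted = 0 <= dp < 2
        rows.append({
            "animal_id": row["animal_id"],
            "day_date": row["day_date"],
            "e_day": e,
            "pn_day": e - GESTATION_DAYS,
            "stage": stage.value,
            "daily_min": row["daily_min"],
            "daily_max": row["daily_max"],
            "n_reads": int(row["n_reads"]),
            "n_bins": int(row["n_bins"]),
            "disrupted": disrupted,
        })
    return pd.DataFrame(rows)


def raster_matrix(binned: pd.DataFrame, bin_minutes: int = BIN_MINUTES_DEFAULT):
    """Day x bin matrix for raster plotting (one animal).

    Returns ``(matrix, day_dates)`` with shape ``(bins_per_day, n_days)``.
    Row 0 is the bin starting at 12:00 noon; rows ascend through the evening
    and night so the active phase is centred; missing bins are NaN.
    Unrolled column-major the matrix is the chronological binned sequence.
    """
    if binned["animal_id"].nunique() > 1:
        raise ValueError("raster_matrix expects a single animal")
    bins_per_day = 1440 // bin_minutes
    days = sorted(binned["day_date"].unique())
    day_pos = {d: j for j, d in enumerate(days)}
    mat = np.full((bins_per_day, len(days)), np.nan)
    rows = binned["bin_index"].to_numpy()
    cols = binned["day_date"].map(day_pos).to_numpy()
    mat[rows, cols] = binned["min_c"].to_numpy()
    return mat, days
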