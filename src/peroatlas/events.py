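"""Threshold-based reproductive event detectors on temperature traces.

The original observations behind these detectors are qualitative: an
extended warm phase past lights-on marks the day of copulation and the day
of birth; rest-phase minima rise ~0.25 degC after copulation and stay up in
a pregnancy, but fall back within a week in a pseudo-pregnancy; a subset of
females show 4-5 day estrous warm days before pairing.  Each detector turns
one of those signatures into an explicit rule with tunable parameters
(:class:`DetectorParams`) that are reported with every call.

All detectors are deterministic given data and parameters.  Per-animal
calibration (the warm threshold and the rest-phase baseline) uses
pre-pairing days only, because male introduction disrupts the rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .features import GESTATION_DAYS

__all__ = [
    "DetectorParams",
    "EventCall",
    "AnimalBaseline",
    "compute_baseline",
    "warm_phase_offset",
    "detect_copulation",
    "classify_pregnancy_course",
    "detect_birth",
    "detect_cyclicity",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunable thresholds of the event detectors (hours, days, degrees C)."""

    copulation_extension_h: float = 3.0
    pregnancy_delta: float = 0.2
    pregnancy_persistence_days: int = 5
    pseudo_reversion_days: int = 7
    birth_elevation_delta: float = 0.5
    cycle_period_band: tuple[float, float] = (3.0, 6.0)
    cycle_prominence: float = 0.2
    bin_minutes: int = 20
    lights_on: float = 6.0
    lights_off: float = 18.0

    def __post_init__(self) -> None:
        if min(self.copulation_extension_h, self.pregnancy_delta,
               self.pregnancy_persistence_days, self.pseudo_reversion_days,
               self.birth_elevation_delta, self.cycle_prominence) <= 0:
            raise ValueError("all detector thresholds must be positive")
        if self.pseudo_reversion_days > GESTATION_DAYS:
            raise ValueError("pseudo_reversion_days must fit inside a pregnancy")


@dataclass
class EventCall:
    animal_id: str
    kind: str  # estrus | copulation | pregnancy_onset | pseudopregnancy | birth
    day_date: object
    score: float
    params: DetectorParams

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("event score must be finite")


@dataclass
class AnimalBaseline:
    """Pre-pairing reference levels for one female."""

    animal_id: str
    rest_median: float
    active_median: float
    daily_min_baseline: float  # median of pre-pairing daily minima
    n_days: int

    @property
    def warm_threshold(self) -> float:
        """Midpoint of rest- and active-phase medians: self-calibrating
        across the ~1.5 degC between-female baseline spread."""
        return 0.5 * (self.rest_median + self.active_median)


def _light_phase_mask(bin_index: np.ndarray, params: DetectorParams) -> np.ndarray:
    """True where a bin (bin 0 = 12:00 noon) starts within the light phase."""
    tod = (12.0 + bin_index * params.bin_minutes / 60.0) % 24.0
    return (tod >= params.lights_on) & (tod < params.lights_off)


def compute_baseline(binned: pd.DataFrame, pairing_date,
                     params: DetectorParams = DetectorParams()) -> AnimalBaseline:
    """Reference medians and mean daily minimum from pre-pairing days."""
    if binned["animal_id"].nunique() > 1:
        raise ValueError("one animal at a time")
    pre = binned[pd.to_datetime(binned["day_date"]) < pd.Timestamp(pairing_date)]
    if pre.empty:
        raise ValueError("no pre-pairing days available for baseline")
    light = _light_phase_mask(pre["bin_index"].to_numpy(), params)
    rest = pre.loc[light, "min_c"]
    active = pre.loc[~light, "min_c"]
    if rest.empty or active.empty:
        raise ValueError("pre-pairing days do not cover both phases")
    daily_min = pre.groupby("day_date")["min_c"].min()
    return AnimalBaseline(
        animal_id=str(binned["animal_id"].iloc[0]),
        rest_median=float(rest.median()),
        active_median=float(active.median()),
        daily_min_baseline=float(daily_min.median()),
        n_days=int(daily_min.size),
    )


def warm_phase_offset(binned_day: pd.DataFrame, baseline: AnimalBaseline,
                      params: DetectorParams = DetectorParams()) -> float:
    """Hours past lights-on that the warm signal persists on one day.

    Scans the 20-minute bins from lights-on forward and returns the end, in
    hours after lights-on, of the contiguous run of bins whose minima exceed
    the warm threshold (0.0 when the signal has already fallen below the
    threshold at lights-on).  The contiguous scan keeps isolated warm bins
    later in the rest phase -- common when a stage elevates rest temperature
    toward the threshold -- from inflating the offset.  Missing bins end the
    run.  Days with more than half their bins missing are rejected.
    """
    bins_per_day = 1440 // params.bin_minutes
    if binned_day["bin_index"].nunique() < bins_per_day // 2:
        raise ValueError("day has <50% bin coverage; warm offset undefined")
    tod = (12.0 + binned_day["bin_index"].to_numpy() * params.bin_minutes / 60.0) % 24.0
    morning = (tod >= params.lights_on) & (tod < 12.0)
    sub = binned_day.loc[morning]
    if sub.empty:
        return 0.0
    by_bin = dict(zip(sub["bin_index"].to_numpy(), sub["min_c"].to_numpy()))
    first_idx = int(round((params.lights_on + 12.0) * 60 / params.bin_minutes))
    n_morning = int(round((12.0 - params.lights_on) * 60 / params.bin_minutes))
    run = 0
    for j in range(n_morning):
        val = by_bin.get(first_idx + j)
        if val is None or val <= baseline.warm_threshold:
            break
        run += 1
    return run * params.bin_minutes / 60.0


def _daily_offsets(binned: pd.DataFrame, baseline: AnimalBaseline,
                   params: DetectorParams) -> pd.Series:
    out = {}
    for day, sub in binned.groupby("day_date", sort=True):
        try:
            out[day] = warm_phase_offset(sub, baseline, params)
        except ValueError:
            continue
    return pd.Series(out, dtype=float)


def detect_copulation(binned: pd.DataFrame, pairing_date,
                      params: DetectorParams = DetectorParams(),
                      baseline: AnimalBaseline | None = None):
    """Call copulation for one female from post-pairing warm extensions.

    Flags every day on/after pairing whose warm-phase offset meets
    ``copulation_extension_h``; the earliest qualifying day is the
    copulation call.  Returns a (possibly empty) list of
    :class:`EventCall`, earliest first.  Never-paired females
    (``pairing_date`` None) yield no calls.
    """
    if pairing_date is None or pd.isna(pairing_date):
        return []
    if baseline is None:
        baseline = compute_baseline(binned, pairing_date, params)
    post = binned[pd.to_datetime(binned["day_date"]) >= pd.Timestamp(pairing_date)]
    offsets = _daily_offsets(post, baseline, params)
    calls = [
        EventCall(baseline.animal_id, "copulation", day, float(off), params)
        for day, off in offsets.items() if off >= params.copulation_extension_h
    ]
    calls.sort(key=lambda c: pd.Timestamp(c.day_date))
    return calls


def classify_pregnancy_course(daily: pd.DataFrame, copulation_call: EventCall,
                              baseline: AnimalBaseline,
                              params: DetectorParams = DetectorParams()) -> str:
    """Classify the days after a copulation call.

    ``"pregnancy"``: daily rest-phase minima sit >= ``pregnancy_delta``
    above the pre-pairing baseline (median of pre-pairing daily minima) on
    at least ``pregnancy_persistence_days`` days of the post-copulation
    window, and the mean elevation in the week after
    ``pseudo_reversion_days`` persists.  ``"pseudopregnancy"``: at least
    two elevated days inside the reversion window but no persistent late
    elevation.  ``"none"``: neither.  ``"indeterminate"``: not enough
    follow-up days to decide.
    """
    cop = pd.Timestamp(copulation_call.day_date)
    sub = daily[daily["animal_id"] == copulation_call.animal_id].copy()
    sub["rel_day"] = (pd.to_datetime(sub["day_date"]) - cop).dt.days
    elev = (sub.set_index("rel_day")["daily_min"] - baseline.daily_min_baseline)

    window = params.pseudo_reversion_days
    early = elev.loc[(elev.index >= 1) & (elev.index <= window)]
    span = elev.loc[(elev.index >= 1) & (elev.index <= window + 5)]
    late = elev.loc[(elev.index >= window + 1) & (elev.index <= window + 7)]
    if len(span) < params.pregnancy_persistence_days or late.empty:
        return "indeterminate"
    n_up = int((span >= params.pregnancy_delta).sum())
    n_early_up = int((early >= params.pregnancy_delta).sum())
    late_up = bool(late.mean() >= params.pregnancy_delta)
    if n_up >= params.pregnancy_persistence_days and late_up:
        return "pregnancy"
    if n_early_up >= 2 and not late_up:
        return "pseudopregnancy"
    return "none"


def detect_birth(binned: pd.DataFrame, daily: pd.DataFrame,
                 copulation_call: EventCall, baseline: AnimalBaseline,
                 params: DetectorParams = DetectorParams()) -> EventCall | None:
    """Call the day of birth for one classified pregnancy.

    Birth requires the conjunction of the two signatures: a warm phase
    extended >= ``copulation_extension_h`` past lights-on, and the daily
    minima of the following five days elevated >= ``birth_elevation_delta``
    above the pre-pairing baseline.  The earliest qualifying day in a
    +/-5-day window around the expected term (copulation + 23 d) is called
    (lactation holds rest temperature near the warm threshold, so later
    days can show spuriously long warm phases); the score is extension
    hours plus subsequent elevation.  Returns None if no day qualifies.
    """
    cop = pd.Timestamp(copulation_call.day_date)
    lo, hi = cop + pd.Timedelta(days=GESTATION_DAYS - 5), cop + pd.Timedelta(days=GESTATION_DAYS + 5)
    sub = binned[(pd.to_datetime(binned["day_date"]) >= lo)
                 & (pd.to_datetime(binned["day_date"]) <= hi)]
    offsets = _daily_offsets(sub, baseline, params)
    d = daily[daily["animal_id"] == copulation_call.animal_id]
    dmin = d.set_index(pd.to_datetime(d["day_date"]))["daily_min"].sort_index()

    for day in sorted(offsets.index, key=pd.Timestamp):
        off = offsets[day]
        if off < params.copulation_extension_h:
            continue
        t0 = pd.Timestamp(day)
        after = dmin.loc[t0:t0 + pd.Timedelta(days=4)]
        if after.empty:
            continue
        elev = float(after.mean() - baseline.daily_min_baseline)
        if elev < params.birth_elevation_delta:
            continue
        return EventCall(baseline.animal_id, "birth", day, off + elev, params)
    return None


def detect_cyclicity(pre_daily_min: pd.Series,
                     params: DetectorParams = DetectorParams()):
    """Detect estrous cyclicity from pre-pairing daily minima.

    ``pre_daily_min`` is a Series of daily rest-phase minima indexed by day
    (in order).  The female is called cycling when at least two peaks of
    prominence >= ``cycle_prominence`` recur at a spacing inside
    ``cycle_period_band``.  Returns ``(status, estrus_positions)`` where
    status is ``"cycling"``, ``"non-cycling"`` or ``"indeterminate"``
    (fewer than five usable days) and positions are integer offsets into
    the series.
    """
    vals = pre_daily_min.to_numpy(dtype=float)
    if np.sum(np.isfinite(vals)) < 5:
        return "indeterminate", []
    peaks, _ = find_peaks(vals, prominence=params.cycle_prominence)
    if len(peaks) < 2:
        return "non-cycling", []
    spacing = np.diff(peaks)
    lo, hi = params.cycle_period_band
    if np.median(spacing) < lo or np.median(spacing) > hi:
        return "non-cycling", []
    return "cycling", [int(p) for p in peaks]
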