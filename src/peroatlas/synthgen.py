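"""Synthetic PIT-tag temperature cohorts with planted reproductive timelines.

The generator emulates subcutaneous temperature telemetry from singly- and
pair-housed female deer mice: reads every ~3 minutes with timing jitter and
dropout, a 12:12 light:dark circadian rhythm with a warm (active) dark phase,
between-female baseline spread, additive reproductive-stage effects on
rest-phase and active-phase temperature, optional estrous warm days, optional
pseudo-pregnancy with reversion, and spurious sensor reads.  Every planted
quantity is returned as a :class:`TruthRecord`, so downstream cleaning,
feature extraction, staging, model fitting and event detection can be
validated against known ground truth.

Time conventions
----------------
The simulated "day" runs from 12:00 (noon) to 11:59 the next morning, which
keeps the dark/active phase contiguous within a day.  Day index 0 starts at
noon of ``start_date``; reproductive-stage effects switch at these noon
boundaries.  Embryonic days (e-days) count from the copulation day, postnatal
days (pn-days) from the birth day; the birth day is e23 and pn0 at once.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "GESTATION_DAYS",
    "IMPLANTATION_E_DAY",
    "WEANING_PN_DAY",
    "GeneratorConfig",
    "TruthRecord",
    "circadian_profile",
    "circadian_weight",
    "simulate_cohort",
    "inject_artifacts",
    "simulate_null_daily",
    "metadata_from_truths",
]

#: Gestation length in days (copulation day e0 through birth day e23).
GESTATION_DAYS = 23
#: First implanted embryonic day.
IMPLANTATION_E_DAY = 6
#: Pups are weaned on this postnatal day.
WEANING_PN_DAY = 22


def _wrap12(hours: np.ndarray) -> np.ndarray:
    """Wrap hour differences into (-12, 12]."""
    return -((-np.asarray(hours, dtype=float) + 12.0) % 24.0 - 12.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    All temperatures are in degrees Celsius, times of day in hours (0-24,
    local clock), and day indices in noon-to-noon days from ``start_date``.
    Stage-effect defaults are the effect sizes the generator plants and that
    the analysis pipeline is expected to recover.
    """

    n_females: int = 9
    start_date: dt.date = dt.date(2024, 1, 1)
    lights_on: float = 6.0
    lights_off: float = 18.0

    # sampling process
    sample_interval_min: float = 3.0
    jitter_sd_min: float = 0.5
    dropout_rate: float = 0.05
    spurious_rate: float = 0.05
    spurious_magnitude: tuple[float, float] = (2.0, 8.0)

    # circadian baseline
    baseline_rest_mean: float = 36.0
    baseline_between_female_sd: float = 0.5
    circadian_amplitude: float = 1.5
    transition_sharpness: float = 4.0

    # within-animal noise
    ar1_rho: float = 0.8
    noise_sd: float = 0.15
    white_noise_sd: float = 0.05

    # reproductive stage effects (additive, degrees C)
    copulation_shift: float = 0.25
    implantation_extra_shift: float = 0.375
    gestation_max_drift: float = -0.25
    nearbirth_min_drop: float = 0.25
    nearbirth_max_cap: float = 0.25
    birthday_warm_extension_h: float = 4.0
    copulation_warm_extension_h: float = 4.0
    lactation_min_shift: float = 0.75
    lactation_max_shift: float = 0.5
    pn8_min_decline: float = 0.25
    pn8_max_decline: float = 0.5

    # estrous cyclicity
    cycling_fraction: float = 4.0 / 14.0
    cycle_period_days: int = 4
    cycle_estrus_rest_bump: float = 0.4

    # pseudo-pregnancy
    pseudopregnant_fraction: float = 0.0
    reversion_days: int = 6

    # housing timeline
    prepairing_days: int = 10
    copulation_delay_days: tuple[int, int] = (1, 3)
    paired: bool = True
    total_days: int | None = None
    missing_day: bool = False

    # male-introduction disruption
    disruption_days: int = 2
    disruption_attenuation: float = 0.15
    disruption_phase_advance_h: float = 2.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "spurious_rate", "cycling_fraction",
                     "pseudopregnant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sample_interval_min <= 0:
            raise ValueError("sample_interval_min must be > 0")
        if self.implantation_extra_shift != 0.0 and not (
                0.25 <= self.implantation_extra_shift <= 0.5):
            # 0.0 switches the effect off entirely (null cohorts)
            raise ValueError(
                "implantation_extra_shift outside the admissible 0.25-0.5 band"
            )
        if not 3 <= self.cycle_period_days <= 6:
            raise ValueError("cycle_period_days must be in [3, 6]")
        if self.reversion_days > 7:
            raise ValueError("reversion_days must be <= 7 (reversion within a week)")
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")

    def zero_effects(self) -> "GeneratorConfig":
        """A copy with every reproductive effect and artifact zeroed.

        Noise terms stay on; this is the null cohort used for detector
        false-positive checks and type-I error simulation.
        """
        return dataclasses.replace(
            self,
            copulation_shift=0.0, implantation_extra_shift=0.0,
            gestation_max_drift=0.0, nearbirth_min_drop=0.0,
            nearbirth_max_cap=0.0, birthday_warm_extension_h=0.0,
            copulation_warm_extension_h=0.0, lactation_min_shift=0.0,
            lactation_max_shift=0.0, pn8_min_decline=0.0, pn8_max_decline=0.0,
            cycling_fraction=0.0, cycle_estrus_rest_bump=0.0,
            pseudopregnant_fraction=0.0,
            disruption_attenuation=0.0, disruption_phase_advance_h=0.0,
        )

    def noiseless(self) -> "GeneratorConfig":
        """A copy with all noise, jitter, dropout and artifacts removed."""
        return dataclasses.replace(
            self, jitter_sd_min=0.0, dropout_rate=0.0, spurious_rate=0.0,
            baseline_between_female_sd=0.0, noise_sd=0.0, white_noise_sd=0.0,
        )


@dataclass
class TruthRecord:
    """Planted ground truth for one simulated female."""

    animal_id: str
    baseline_offset: float
    cycling: bool
    estrus_days: list[int]
    pseudopregnant: bool
    male_intro_day: int | None
    pseudo_copulation_day: int | None
    copulation_day: int | None
    implantation_day: int | None
    birth_day: int | None
    weaning_day: int | None
    shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.copulation_day is not None:
            assert self.implantation_day == self.copulation_day + IMPLANTATION_E_DAY
            assert self.birth_day == self.copulation_day + GESTATION_DAYS
            assert self.weaning_day == self.birth_day + WEANING_PN_DAY


def circadian_weight(
    time_of_day_h,
    cfg: GeneratorConfig,
    lights_on_shift_h=0.0,
    phase_advance_h=0.0,
):
    """Normalized activity weight in [0, 1] at a clock time (hours).

    A smoothed square wave built from two logistic transitions: 0 exactly at
    the middle of the light (rest) phase, 1 exactly at the middle of the dark
    (active) phase.  ``lights_on_shift_h`` extends the warm phase past
    lights-on on that morning (copulation/birth-day warm extensions);
    ``phase_advance_h`` advances the whole rhythm (male-introduction
    disruption).
    """
    tod_clock = np.asarray(time_of_day_h, dtype=float)
    tod = tod_clock + phase_advance_h
    s = cfg.transition_sharpness
    a = _wrap12(tod - cfg.lights_off)
    b = _wrap12(cfg.lights_on - tod)
    raw = _sigmoid(s * a) * _sigmoid(s * b)
    half_dark = _wrap12(cfg.lights_on - cfg.lights_off) / 2.0
    wmax = _sigmoid(s * half_dark) ** 2
    wmin = _sigmoid(-s * (12.0 - half_dark)) ** 2
    w = np.clip((raw - wmin) / (wmax - wmin), 0.0, 1.0)
    shift = np.broadcast_to(np.asarray(lights_on_shift_h, dtype=float), w.shape)
    if np.any(shift > 0):
        # hold the plateau through the extended morning, then decay with the
        # usual logistic transition ending at lights-on + shift; anchored to
        # clock time so a phase-advanced rhythm still extends past lights-on
        ramp = _sigmoid(s * (cfg.lights_on + shift - tod_clock))
        w = np.where(shift > 0, np.maximum(w, ramp), w)
    return w


def circadian_profile(time_of_day_h, cfg: GeneratorConfig):
    """Deterministic 24 h-periodic temperature baseline (degrees C).

    Minimum (mid light phase) equals ``baseline_rest_mean`` exactly; the
    dark-phase plateau sits ``circadian_amplitude`` above it.
    """
    w = circadian_weight(time_of_day_h, cfg)
    return cfg.baseline_rest_mean + cfg.circadian_amplitude * w


def _horizon_days(cfg: GeneratorConfig, latest_weaning: int) -> int:
    if cfg.total_days is not None:
        if cfg.paired and cfg.total_days < latest_weaning + 1:
            raise ValueError(
                f"total_days={cfg.total_days} is shorter than the latest "
                f"copulation + gestation + weaning horizon ({latest_weaning + 1} d)"
            )
        return cfg.total_days
    return latest_weaning + 2 if cfg.paired else cfg.prepairing_days + 2


def _plan_timelines(cfg: GeneratorConfig, rng: np.random.Generator) -> list[TruthRecord]:
    n = cfg.n_females
    n_cycling = int(round(cfg.cycling_fraction * n))
    cycling_ids = rng.choice(n, size=n_cycling, replace=False)
    n_pseudo = int(round(cfg.pseudopregnant_fraction * n))
    pseudo_ids = rng.choice(n, size=n_pseudo, replace=False)
    lo, hi = cfg.copulation_delay_days
    truths: list[TruthRecord] = []
    for i in range(n):
        cycling = i in cycling_ids
        pseudo = i in pseudo_ids
        phase = int(rng.integers(0, cfg.cycle_period_days))
        estrus = (
            list(range(phase, cfg.prepairing_days, cfg.cycle_period_days))
            if cycling else []
        )
        male_intro = cfg.prepairing_days if cfg.paired else None
        pseudo_day = cop = None
        if cfg.paired:
            delay = int(rng.integers(lo, hi + 1))
            if pseudo:
                pseudo_day = male_intro + delay
                # conception resumes a full estrous cycle after the
                # pseudo-pregnant elevation has reverted
                cop = pseudo_day + cfg.reversion_days + cfg.cycle_period_days + 2
            else:
                cop = male_intro + delay
        shifts = {
            "pre_implantation_min": cfg.copulation_shift,
            "gestation_min": cfg.copulation_shift + cfg.implantation_extra_shift,
            "gestation_max": cfg.gestation_max_drift,
            "nearbirth_min": (cfg.copulation_shift + cfg.implantation_extra_shift
                              - cfg.nearbirth_min_drop),
            "nearbirth_max": -cfg.nearbirth_max_cap,
            "early_postnatal_min": cfg.lactation_min_shift,
            "early_postnatal_max": cfg.lactation_max_shift,
            "mid_late_postnatal_min": cfg.lactation_min_shift - cfg.pn8_min_decline,
            "mid_late_postnatal_max": cfg.lactation_max_shift - cfg.pn8_max_decline,
        }
        truths.append(TruthRecord(
            animal_id=f"F{i + 1:02d}",
            baseline_offset=float(rng.normal(0.0, cfg.baseline_between_female_sd)),
            cycling=cycling,
            estrus_days=estrus,
            pseudopregnant=pseudo,
            male_intro_day=male_intro,
            pseudo_copulation_day=pseudo_day,
            copulation_day=cop,
            implantation_day=None if cop is None else cop + IMPLANTATION_E_DAY,
            birth_day=None if cop is None else cop + GESTATION_DAYS,
            weaning_day=None if cop is None else cop + GESTATION_DAYS + WEANING_PN_DAY,
            shifts=shifts,
        ))
    return truths


def _day_effect_tables(cfg: GeneratorConfig, truth: TruthRecord, n_days: int):
    """Per-day additive offsets for rest (r) and active (a) temperature,
    amplitude factor, phase advance and morning warm-extension hours."""
    r = np.zeros(n_days)
    a = np.zeros(n_days)
    ampf = np.ones(n_days)
    adv = np.zeros(n_days)
    ext = np.zeros(n_days)

    for d in truth.estrus_days:
        if d < n_days:
            r[d] += cfg.cycle_estrus_rest_bump

    if truth.pseudo_copulation_day is not None:
        pd_ = truth.pseudo_copulation_day
        r[pd_:min(pd_ + cfg.reversion_days, n_days)] += cfg.copulation_shift
        if pd_ < n_days:
            ext[pd_] = cfg.copulation_warm_extension_h

    if truth.copulation_day is not None:
        cop, birth = truth.copulation_day, truth.birth_day
        sh = truth.shifts

        def _set(arr, start, stop, value):
            arr[max(start, 0):min(stop, n_days)] += value

        _set(r, cop, cop + 6, sh["pre_implantation_min"])
        _set(r, cop + 6, cop + 21, sh["gestation_min"])
        _set(r, cop + 21, cop + 23, sh["nearbirth_min"])
        _set(a, cop + 6, cop + 21, sh["gestation_max"])
        _set(a, cop + 21, cop + 23, sh["nearbirth_max"])
        _set(r, birth, birth + 9, sh["early_postnatal_min"])
        _set(r, birth + 9, birth + 23, sh["mid_late_postnatal_min"])
        _set(a, birth, birth + 9, sh["early_postnatal_max"])
        _set(a, birth + 9, birth + 23, sh["mid_late_postnatal_max"])
        if cop < n_days:
            ext[cop] = cfg.copulation_warm_extension_h
        if birth < n_days:
            ext[birth] = cfg.birthday_warm_extension_h

    if truth.male_intro_day is not None and cfg.disruption_days > 0:
        mi = truth.male_intro_day
        ampf[mi:min(mi + cfg.disruption_days, n_days)] *= 1.0 - cfg.disruption_attenuation
        adv[mi:min(mi + cfg.disruption_days, n_days)] = cfg.disruption_phase_advance_h
    return r, a, ampf, adv, ext


def _simulate_female(cfg: GeneratorConfig, truth: TruthRecord, n_days: int,
                     missing_day: int | None, rng: np.random.Generator) -> pd.DataFrame:
    total_min = n_days * 1440.0
    n_sched = int(total_min / cfg.sample_interval_min)
    t_min = np.arange(n_sched) * cfg.sample_interval_min
    if cfg.jitter_sd_min > 0:
        t_min = t_min + rng.normal(0.0, cfg.jitter_sd_min, n_sched)
        t_min = np.sort(np.clip(t_min, 0.0, total_min - 1e-6))
    keep = rng.random(n_sched) >= cfg.dropout_rate
    t_min = t_min[keep]

    day = np.minimum((t_min // 1440.0).astype(int), n_days - 1)
    tod = (t_min / 60.0 + 12.0) % 24.0

    r, a, ampf, adv, ext = _day_effect_tables(cfg, truth, n_days)

    # warm-phase extension applies to the morning (past lights-on) at the end
    # of the flagged noon-to-noon day
    ext_read = np.where(
        (tod >= cfg.lights_on) & (tod < 12.0), ext[day], 0.0
    )
    w = circadian_weight(tod, cfg, lights_on_shift_h=ext_read,
                         phase_advance_h=adv[day])
    amp = cfg.circadian_amplitude * ampf[day]
    temp = (cfg.baseline_rest_mean + truth.baseline_offset
            + amp * w + r[day] * (1.0 - w) + a[day] * w)

    m = temp.size
    if cfg.noise_sd > 0 and m > 0:
        innov = rng.normal(0.0, cfg.noise_sd * np.sqrt(1 - cfg.ar1_rho ** 2), m)
        innov[0] = rng.normal(0.0, cfg.noise_sd)
        temp = temp + lfilter([1.0], [1.0, -cfg.ar1_rho], innov)
    if cfg.white_noise_sd > 0 and m > 0:
        temp = temp + rng.normal(0.0, cfg.white_noise_sd, m)

    df = pd.DataFrame({
        "animal_id": truth.animal_id,
        "timestamp": (pd.Timestamp(cfg.start_date) + pd.Timedelta(hours=12)
                      + pd.to_timedelta(np.round(t_min * 60.0), unit="s")),
        "temp_c": temp,
        "artifact": False,
    })
    df, _ = inject_artifacts(df, cfg.spurious_rate, 0.0, rng=rng,
                             magnitude=cfg.spurious_magnitude)
    if missing_day is not None:
        start = (pd.Timestamp(cfg.start_date) + pd.Timedelta(hours=12)
                 + pd.Timedelta(days=missing_day))
        gone = (df["timestamp"] >= start) & (df["timestamp"] < start + pd.Timedelta(days=1))
        df = df.loc[~gone].reset_index(drop=True)
    return df


def simulate_cohort(cfg: GeneratorConfig, seed: int | None = None):
    """Simulate a cohort of females.

    Returns ``(traces, truths)`` where ``traces`` is a tidy DataFrame with
    columns ``animal_id, timestamp, temp_c, artifact`` (the last is the
    ground-truth spurious-read mask) and ``truths`` is one
    :class:`TruthRecord` per female.  Fixing the seed fixes the output
    bit-for-bit.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    truths = _plan_timelines(cfg, rng)
    latest = max((t.weaning_day for t in truths if t.weaning_day is not None),
                 default=0)
    n_days = _horizon_days(cfg, latest)
    missing = None
    if cfg.missing_day:
        missing = int(rng.integers(n_days // 3, 2 * n_days // 3))
    frames = [_simulate_female(cfg, t, n_days, missing, rng) for t in truths]
    return pd.concat(frames, ignore_index=True), truths


def inject_artifacts(trace: pd.DataFrame, spurious_rate: float,
                     dropout_rate: float, seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     magnitude: tuple[float, float] = (2.0, 8.0)):
    """Inject spurious displaced reads and dropout into a trace.

    Spurious reads are displaced by a random sign times a uniform draw from
    ``magnitude`` (degrees C).  Returns ``(trace, artifact_mask)``; the mask
    is also stored in the ``artifact`` column.  Selection uses one uniform
    draw per read compared against the rate, so at a fixed seed the artifact
    sets are nested across rates.
    """
    if not 0.0 <= spurious_rate <= 1.0 or not 0.0 <= dropout_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = trace.copy()
    n = len(out)
    u_spur = rng.random(n)
    offs = rng.uniform(magnitude[0], magnitude[1], n) * rng.choice([-1.0, 1.0], n)
    u_drop = rng.random(n)
    spur = u_spur < spurious_rate
    out.loc[spur, "temp_c"] = out.loc[spur, "temp_c"] + offs[spur]
    if "artifact" in out.columns:
        out["artifact"] = out["artifact"].to_numpy() | spur
    else:
        out["artifact"] = spur
    if dropout_rate > 0:
        keep = u_drop >= dropout_rate
        out = out.loc[keep].reset_index(drop=True)
        return out, out["artifact"].to_numpy()
    return out, spur


def simulate_null_daily(n_females: int, stages, days_per_stage: int,
                        sd_animal: float = 0.5, sd_resid: float = 0.1,
                        rng: np.random.Generator | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Daily-summary table under the null (no stage effects).

    Draws a random intercept per female and i.i.d. residuals per
    female-stage-day; used for family-wise type-I error simulation of the
    stage model without paying for full trace simulation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    stages = list(stages)
    base = rng.normal(0.0, sd_animal, n_females)
    rows = []
    for i in range(n_females):
        for st in stages:
            vals = base[i] + rng.normal(0.0, sd_resid, days_per_stage)
            for v in vals:
                rows.append((f"F{i + 1:02d}", st, float(v)))
    return pd.DataFrame(rows, columns=["animal_id", "stage", "value"])


def metadata_from_truths(cfg: GeneratorConfig, truths) -> pd.DataFrame:
    """Per-animal metadata table as a field user would record it.

    Pairing and birth dates are calendar dates of the noon-to-noon day on
    which each event falls; the estimated copulation date is *not* included
    (it is re-derived from the observed birth date downstream).
    """
    start = pd.Timestamp(cfg.start_date)

    def _date(d):
        return None if d is None else (start + pd.Timedelta(days=int(d))).date()

    return pd.DataFrame([
        {
            "animal_id": t.animal_id,
            "pairing_date": _date(t.male_intro_day),
            "birth_date": _date(t.birth_day),
            "weaning_date": _date(t.weaning_day),
            "lights_on": cfg.lights_on,
            "lights_off": cfg.lights_off,
        }
        for t in truths
    ])
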