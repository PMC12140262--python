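"""Spurious-read filtering for PIT-tag temperature traces.

A read is retained when it falls within ``k`` robust standard deviations of
an 11-read rolling median.  The robust SD is computed once per animal as the
median of the sample SDs of every complete window, which keeps windows that
happen to contain an extreme value from inflating the local scale estimate.
The filter makes a single pass; removed reads are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CleaningParams",
    "CleaningReport",
    "rolling_window_stats",
    "robust_sd",
    "clean_trace",
]


@dataclass(frozen=True)
class CleaningParams:
    """Filter settings.

    window
        Number of reads per rolling window (odd, >= 3).
    k
        Retention half-width in multiples of the robust SD.
    alignment
        ``"centered"`` (symmetric window, the default) or ``"trailing"``.
    """

    window: int = 11
    k: float = 1.5
    alignment: str = "centered"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.alignment not in ("centered", "trailing"):
            raise ValueError("alignment must be 'centered' or 'trailing'")


@dataclass
class CleaningReport:
    """Per-animal summary of one filtering pass."""

    animal_id: str
    reads_in: int
    reads_retained: int
    retention_fraction: float
    robust_sd: float
    n_gaps_over_6h: int = 0


def rolling_window_stats(values, window: int = 11, alignment: str = "centered"):
    """Rolling median and sample SD per position.

    Windows slide one read at a time.  Interior positions use complete
    windows; positions near the sequence edge use truncated windows of at
    least ``(window + 1) // 2`` reads so that edge reads still receive a
    local median.  SDs use the n-1 (sample) convention and are returned as
    NaN where the window is incomplete.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if values.size < window:
        raise ValueError(
            f"sequence length {values.size} is shorter than window {window}"
        )
    s = pd.Series(values)
    center = alignment == "centered"
    min_periods = (window + 1) // 2
    medians = s.rolling(window, center=center, min_periods=min_periods).median()
    sds = s.rolling(window, center=center, min_periods=window).std(ddof=1)
    return medians.to_numpy(), sds.to_numpy()


def robust_sd(values, window: int = 11, alignment: str = "centered") -> float:
    """Median of the sample SDs of every complete rolling window."""
    _, sds = rolling_window_stats(values, window, alignment)
    return float(np.nanmedian(sds))


def clean_trace(trace: pd.DataFrame, params: CleaningParams = CleaningParams(),
                temp_col: str = "temp_c"):
    """Filter one animal's time-sorted trace.

    Returns ``(mask, report)`` where ``mask`` is a boolean array aligned with
    the input rows (True = retained).  Read *i* is retained when
    ``|temp_i - rolling_median_i| <= k * robust_sd`` (ties retained).  Gaps
    longer than 6 h do not reset the windows (windows count reads, not
    time) but are tallied in the report.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if trace["animal_id"].nunique() > 1:
        raise ValueError("clean_trace operates on a single animal")
    values = trace[temp_col].to_numpy(dtype=float)
    if values.size < params.window:
        raise ValueError(
            f"trace has {values.size} reads, fewer than window={params.window}"
        )
    medians, _ = rolling_window_stats(values, params.window, params.alignment)
    sd = robust_sd(values, params.window, params.alignment)
    mask = np.abs(values - medians) <= params.k * sd

    n_gaps = 0
    if "timestamp" in trace.columns and len(trace) > 1:
        dt_h = trace["timestamp"].diff().dt.total_seconds().to_numpy()[1:] / 3600.0
        n_gaps = int(np.sum(dt_h > 6.0))

    report = CleaningReport(
        animal_id=str(trace["animal_id"].iloc[0]),
        reads_in=int(values.size),
        reads_retained=int(mask.sum()),
        retention_fraction=float(mask.mean()),
        robust_sd=sd,
        n_gaps_over_6h=n_gaps,
    )
    return mask, report


def clean_cohort(traces: pd.DataFrame, params: CleaningParams = CleaningParams()):
    """Apply :func:`clean_trace` per animal; returns (cleaned, reports).

    ``cleaned`` keeps only retained rows; ``reports`` is a DataFrame with one
    row per animal mirroring :class:`CleaningReport`.
    """
    cleaned, reports = [], []
    for aid, sub in traces.groupby("animal_id", sort=True):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        mask, rep = clean_trace(sub, params)
        cleaned.append(sub.loc[mask])
        reports.append(rep.__dict__)
    return (pd.concat(cleaned, ignore_index=True),
            pd.DataFrame(reports))
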