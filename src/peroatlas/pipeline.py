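"""End-to-end helpers chaining simulate -> clean -> features -> stats.

These are thin orchestration functions used by the CLI, the acceptance
script and the test suite; all science lives in the per-step modules.
"""

from __future__ import annotations

import pandas as pd

from . import cleaning, features, stagestats, synthgen

__all__ = ["cohort_daily", "cohort_contrasts", "CONTRAST_KEYS"]


def cohort_daily(cfg: synthgen.GeneratorConfig, seed: int | None = None,
                 params: cleaning.CleaningParams = cleaning.CleaningParams()):
    """Simulate one cohort and run it through cleaning and daily extrema.

    Returns a dict with the raw traces, truths, cleaned traces, cleaning
    reports, binned minima, anchored timelines and the daily summary table.
    """
    traces, truths = synthgen.simulate_cohort(cfg, seed=seed)
    cleaned, reports = cleaning.clean_cohort(traces, params)
    metadata = synthgen.metadata_from_truths(cfg, truths)
    timelines = features.timelines_from_metadata(metadata)
    binned = features.bin_minima(cleaned)
    daily = features.daily_extrema(cleaned, timelines)
    return {
        "traces": traces, "truths": truths, "cleaned": cleaned,
        "reports": reports, "metadata": metadata, "timelines": timelines,
        "binned": binned, "daily": daily,
    }


#: named stage contrasts of interest: (response, stage_a, stage_b)
CONTRAST_KEYS = {
    "preimpl_minus_nonpreg_min": ("min", "PRE_IMPLANTATION", "NON_PREGNANT"),
    "gestation_minus_preimpl_min": ("min", "GESTATION", "PRE_IMPLANTATION"),
    "nonpreg_minus_gestation_max": ("max", "NON_PREGNANT", "GESTATION"),
    "earlypn_minus_nonpreg_min": ("min", "EARLY_POSTNATAL", "NON_PREGNANT"),
    "earlypn_minus_nonpreg_max": ("max", "EARLY_POSTNATAL", "NON_PREGNANT"),
    "earlypn_minus_midlatepn_max": ("max", "EARLY_POSTNATAL", "MID_LATE_POSTNATAL"),
}


def cohort_contrasts(daily: pd.DataFrame, alpha: float = 0.05,
                     adjust: str = "tukey"):
    """Fit min and max stage models and extract the named contrasts.

    Returns ``(values, fits)`` where ``values`` maps each CONTRAST_KEYS name
    to the estimated difference (degrees C) and ``fits`` holds both fitted
    models plus their contrast tables and letters.
    """
    fits = {}
    for response in ("min", "max"):
        fit = stagestats.fit_stage_model(daily, response=response)
        contrasts, letters = stagestats.pairwise_contrasts(fit, alpha=alpha,
                                                           adjust=adjust)
        fits[response] = {"fit": fit, "contrasts": contrasts, "letters": letters}
    values = {}
    for name, (resp, a, b) in CONTRAST_KEYS.items():
        means = fits[resp]["fit"].stage_means
        if a in means and b in means:
            values[name] = means[a] - means[b]
    return values, fits


def stage_mean_min_range(daily: pd.DataFrame) -> float:
    """Across-female range of per-female stage-mean daily minima, averaged
    over stages (the between-individual spread statistic)."""
    g = daily.groupby(["stage", "animal_id"], observed=True)["daily_min"].mean()
    per_stage = g.groupby(level="stage", observed=True).agg(lambda s: s.max() - s.min())
    return float(per_stage.mean())
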