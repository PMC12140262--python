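import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from peroatlas import cleaning, events, pipeline
from peroatlas.synthgen import GeneratorConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: seeds used for every multi-seed recovery check
COHORT_SEEDS = tuple(range(1, 21))


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """One default 9-female cohort run through the full pipeline."""
    return pipeline.cohort_daily(default_cfg, seed=1)


def _summarize(cfg, seed):
    """Run one cohort and keep only the small derived tables plus
    cleaning-vs-truth summaries (full traces are too big to keep x20)."""
    res = pipeline.cohort_daily(cfg, seed=seed)
    traces = res["traces"]
    # per-cohort cleaning performance against the planted artifact mask
    removed_frac = []
    clean_removed_frac = []
    for aid, sub in traces.groupby("animal_id"):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        mask, _ = cleaning.clean_trace(sub)
        art = sub["artifact"].to_numpy()
        removed_frac.append(np.mean(~mask[art]))
        clean_removed_frac.append(np.mean(~mask[~art]))
    return {
        "truths": res["truths"],
        "metadata": res["metadata"],
        "binned": res["binned"],
        "daily": res["daily"],
        "reports": res["reports"],
        "artifact_removal": float(np.mean(removed_frac)),
        "clean_removal": float(np.mean(clean_removed_frac)),
    }


@pytest.fixture(scope="session")
def multi_cohorts(default_cfg):
    """Twenty default cohorts (seeds 1-20), summarized."""
    return [_summarize(default_cfg, seed) for seed in COHORT_SEEDS]


@pytest.fixture(scope="session")
def contrast_table(multi_cohorts):
    """Named stage contrasts and spread statistic per cohort."""
    rows = []
    for res in multi_cohorts:
        vals, _ = pipeline.cohort_contrasts(res["daily"])
        vals["stage_mean_min_range"] = pipeline.stage_mean_min_range(res["daily"])
        rows.append(vals)
    return pd.DataFrame(rows)


def run_detectors(res, start_date):
    """Run all event detectors for each female of a summarized cohort.

    Returns per-female dicts with called vs planted day indices.
    """
    start = pd.Timestamp(start_date)
    meta, binned, daily = res["metadata"], res["binned"], res["daily"]
    out = []
    for t in res["truths"]:
        sub = binned[binned["animal_id"] == t.animal_id]
        pairing = meta.loc[meta["animal_id"] == t.animal_id, "pairing_date"].iloc[0]
        rec = {"truth": t, "cop_called": None, "birth_called": None,
               "course": None, "cycling_called": None}
        if pairing is not None and not pd.isna(pairing):
            base = events.compute_baseline(sub, pairing)
            pre = sub[pd.to_datetime(sub["day_date"]) < pd.Timestamp(pairing)]
            status, _ = events.detect_cyclicity(
                pre.groupby("day_date")["min_c"].min())
            rec["cycling_called"] = status == "cycling"
            calls = events.detect_copulation(sub, pairing, baseline=base)
            if calls:
                rec["cop_called"] = (pd.Timestamp(calls[0].day_date) - start).days
                da = daily[daily["animal_id"] == t.animal_id]
                rec["course"] = events.classify_pregnancy_course(da, calls[0], base)
                birth = events.detect_birth(sub, da, calls[0], base)
                if birth is not None:
                    rec["birth_called"] = (pd.Timestamp(birth.day_date) - start).days
        out.append(rec)
    return out


@pytest.fixture(scope="session")
def pseudo_cohorts(default_cfg):
    cfg = dataclasses.replace(default_cfg, n_females=5,
                              pseudopregnant_fraction=1.0)
    return cfg, [_summarize(cfg, seed) for seed in range(1, 9)]


@pytest.fixture(scope="session")
def null_cohorts(default_cfg):
    cfg = default_cfg.zero_effects()
    return cfg, [_summarize(cfg, seed) for seed in range(1, 9)]
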