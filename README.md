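# peroatlas

Tools for analysing continuous body-temperature telemetry across
reproduction in the North American deer mouse (*Peromyscus maniculatus*),
plus placental section morphometry — with a first-class synthetic-data
generator so the whole pipeline is verifiable against planted ground truth.

## Who this is for

Reproductive physiologists and behavioural ecologists working with
PIT-tag / RFID temperature loggers in small rodents, who want to

* clean spurious sensor reads the way the deer-mouse gestational-atlas
  pipeline does,
* detect estrous cyclicity, copulation, pregnancy vs pseudo-pregnancy and
  birth from temperature alone,
* quantify how daily temperature extrema change across reproductive stages
  with a mixed model, and
* quantify placental zone areas and labyrinth blood-space fractions from
  label masks.

## The models in brief

**Cleaning.** A read `x_i` is retained iff `|x_i − med_i| ≤ k·ŝ`, where
`med_i` is the centred 11-read rolling median and `ŝ` is the *median* of the
sample SDs of all complete 11-read windows for that animal (robust to the
windows that happen to contain extreme values); `k = 1.5`.

**Features.** Days run noon-to-noon so the dark (active) phase is
contiguous. Traces are anchored on the estimated copulation day
(`e0 = observed birth − 23 d`); minima are taken in 20-minute bins
(72/day), and each anchored day gets one daily minimum/maximum and a
reproductive-stage label: non-pregnant (< e0), pre-implantation (e0–e5),
gestation (e6–e20), near-birth (e21–e22), early postnatal (e23 = pn0
through pn8), mid-to-late postnatal (pn9–pn22).

**Stage statistics.** Daily extrema are modelled as
`y_ij = μ + β_stage(ij) + u_i + ε_ij` with a random intercept `u_i` per
female (REML, statsmodels `MixedLM`). All pairwise stage contrasts are
tested with Tukey (studentized-range) adjustment at α = 0.05 and summarized
by a compact letter display.

**Event detection.** Each animal is self-calibrated from its pre-pairing
days: the warm threshold is the midpoint of its rest- and active-phase
medians. Copulation and birth are flagged by the warm phase persisting ≥3 h
past lights-on; pregnancy requires rest-phase minima ≥0.2 °C above baseline
that persist past a week, pseudo-pregnancy the same elevation reverting
within a week; cyclicity requires ≥0.2 °C rest-phase peaks recurring every
3–6 days.

**Morphometry.** Zone areas are pixel counts × (µm/px)², with per-site
medians over ≥3 sections and relative fractions summing to 1. Labyrinth
compartment fractions (maternal blood / fetal blood / tissue / nuclei
clump) come from point-count stereology: a systematic uniform random grid
of 400 points, fraction SE = √(p(1−p)/400), tissue + nuclei pooled, and
absolute compartment areas = fraction × zone area. Cell counts use a
distance-transform watershed.

**Synthetic data.** `synthgen` simulates reads every ~3 min with jitter,
dropout and spurious outliers on a 12:12 LD smoothed-square-wave rhythm
(warm dark phase), a ~1.5 °C between-female baseline range, and additive
stage effects at the magnitudes the pipeline is expected to recover
(+0.25 °C after copulation, +0.375 °C more at implantation, −0.25 °C
gestational maximum drift, +0.75/+0.5 °C lactation minima/maxima, −0.25/
−0.5 °C pn8 declines), plus optional 4-day estrous warm days, a
pseudo-pregnancy that reverts within a week, and warm-phase extensions on
the copulation and birth mornings. Every planted quantity is returned as a
`TruthRecord`.

## Worked example

```python
from peroatlas import pipeline
from peroatlas.synthgen import GeneratorConfig

cfg = GeneratorConfig()                      # 9 females, default effects
res = pipeline.cohort_daily(cfg, seed=1)     # simulate → clean → stage
vals, fits = pipeline.cohort_contrasts(res["daily"])
for k, v in vals.items():
    print(f"{k:32s} {v:+.3f}")
print(fits["min"]["letters"])
```

prints (seed 1):

```
preimpl_minus_nonpreg_min        +0.227
gestation_minus_preimpl_min      +0.363
nonpreg_minus_gestation_max      +0.220
earlypn_minus_nonpreg_min        +0.721
earlypn_minus_nonpreg_max        +0.531
earlypn_minus_midlatepn_max      +0.503
{'NON_PREGNANT': 'a', 'PRE_IMPLANTATION': 'b', 'NEAR_BIRTH': 'c',
 'MID_LATE_POSTNATAL': 'd', 'GESTATION': 'e', 'EARLY_POSTNATAL': 'f'}
```

The recovered contrasts sit within Monte-Carlo error of the planted
effects (+0.25, +0.375, +0.25, +0.75, +0.5, +0.5 °C), and all six stages
differ significantly on daily minima in this cohort — each stage gets its
own letter. About 93% of reads survive cleaning at the default 5% spurious
rate.

The same steps are available from the shell:

```bash
peroatlas simulate --seed 1 --out cohort/
peroatlas clean --in cohort/traces.csv --out cleaned.csv --report report.tsv
peroatlas features --traces cleaned.csv --metadata cohort/metadata.csv --out feat/
peroatlas stats --daily feat/daily.tsv --response min --out stats/
peroatlas events --traces cohort/traces.csv --metadata cohort/metadata.csv --out events.tsv
peroatlas raster --binned feat/binned.csv --animal F01 --out raster.png
```

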