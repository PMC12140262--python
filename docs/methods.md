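# Methods

This note documents the models, parameter choices and numerical conventions
behind `peroatlas`, and what the synthetic-data validation does and does not
establish about real telemetry.

## Time and day conventions

All clock arithmetic is naive local time (no timezones/DST). An analysis
"day" runs from 12:00 noon to 11:59 the next morning. This keeps the dark
(active) phase of a 12:12 LD nocturnal rodent contiguous inside one day, so
each day contributes exactly one rest-phase minimum and one active-phase
maximum, and matches the raster convention (row 0 = the 12:00 bin at the
bottom of the plot). A midnight-based convention is available through the
binning utilities but is not the default, because it splits the active
phase across two days.

Embryonic days count from the estimated copulation day (`e0 = observed
birth date − 23 d`; gestation is treated as a fixed 23 days for dams that
are not concurrently lactating). Postnatal days count from birth; the birth
day is simultaneously e23 and pn0 and is labelled early-postnatal, because
the extended warm phase on the day of birth groups it with the lactation
signature rather than with the near-birth cooling.

The generator switches its planted stage effects at the same noon
boundaries the analysis uses. This is a deliberate alignment: it makes
every planted shift exactly identifiable from daily extrema. Real
transitions (copulation at night, birth during the day) blur across a day
boundary; the event detectors' ±1-day tolerance reflects that.

## Synthetic cohort generator

The generated temperature is

    T(t) = rest_mean + b_i + A·f(t)·w(t) + r_d·(1 − w(t)) + a_d·w(t) + ε(t)

where `w(t) ∈ [0,1]` is a smoothed square wave (logistic transitions,
sharpness 4 h⁻¹, 10–90% width ≈ 1.1 h) that is exactly 0 at mid-light and
exactly 1 at mid-dark; `b_i ~ N(0, 0.5²)` is the female's baseline offset;
`r_d` and `a_d` are the per-day rest- and active-phase offsets of the
current reproductive stage; `A = 1.5 °C` is the circadian amplitude and
`f(t)` an attenuation factor (< 1 only on the two disrupted days after male
introduction). Noise `ε` is AR(1) with stationary SD 0.15 °C and lag-1
correlation 0.8 over reads, plus white measurement noise (SD 0.05 °C).
Reads are scheduled every 3 min with Gaussian timing jitter (SD 0.5 min),
thinned by 5% dropout, and 5% of reads are displaced by ±(2–8) °C to mimic
spurious PIT-tag reads.

Magnitudes of the planted stage effects are the cohort conditions the
pipeline must recover: +0.25 °C on rest-phase minima after copulation,
+0.375 °C more from implantation (e6, midpoint of the plausible
0.25–0.5 °C band), −0.25 °C on gestational maxima, a 0.25 °C near-birth
minimum drop with maxima capped low, +0.75/+0.5 °C lactation elevation of
minima/maxima through pn8, and −0.25/−0.5 °C declines after pn8. The
between-female SD of 0.5 °C is calibrated so that the expected range across
9 females, 2.97 × 0.5 ≈ 1.5 °C, matches the observed inter-individual
spread. Absolute temperature (36 °C rest) and amplitude (1.5 °C) are
plausible placeholders — the source data report only relative changes — and
everything downstream depends on differences only.

Cohort structure: 10 single-housed (pre-pairing) days, male introduction,
copulation 1–3 days later, birth at copulation + 23, weaning at birth + 22.
4/14 of females cycle before pairing (4-day period, +0.4 °C estrus rest
days). The two days after male introduction get a 2-h phase advance and 15%
amplitude attenuation (rhythm disruption); these days are flagged, not
excluded. Copulation and birth mornings extend the warm plateau 4 h past
lights-on; the extension is anchored to clock lights-on even on
phase-advanced days. Optional pseudo-pregnancy plants the copulation
signature plus a +0.25 °C rest elevation that reverts after 6 days, with a
successful conception one estrous cycle after reversion.

What the generator does *not* emulate: activity bouts and torpor,
temperature dependence on ambient conditions, concurrent
lactation-gestation (second pregnancies), pup temperatures leaking into the
reader, or slow sensor drift. Passing recovery tests therefore shows the
pipeline's estimators are correct and well-calibrated under this additive
model — not that the detectors' default thresholds are optimal for any
particular real dataset; all thresholds are exposed for recalibration.

## Cleaning filter

Retention rule: `|x_i − med_i| ≤ k·ŝ` with `med_i` the centred 11-read
rolling median (ties retained), `k = 1.5`, and `ŝ` the median of the sample
(n−1) SDs of all complete windows for that animal. Edge positions use
truncated windows of ≥6 reads for the median so day-boundary reads survive;
only complete windows contribute SDs. Windows count reads, not time —
gaps > 6 h do not reset the window but are tallied. The alternative
trailing alignment is available; centred is the default (symmetric, no
phase lag at circadian transitions — the centre of a locally monotone ramp
is its own window median, so transitions are not clipped). One pass only.

Operating characteristics measured on synthetic cohorts: at a 5% spurious
rate essentially 100% of planted artifacts are removed and ~93% of reads
are retained. Under the AR(1) noise defaults roughly 7% of *clean* reads
fall outside ±1.5 robust SDs of their window median and are sacrificed;
this is intrinsic to the rule, not a bug, and is consistent with retention
in the high-80s/low-90s percent range on real traces. Known limitation: the
robust SD is a median over windows of which a fraction 1 − (1−ρ)¹¹ contain
at least one artifact at artifact rate ρ; beyond ρ ≈ 10–15% the threshold
inflates enough that removal degrades and retention is *not* monotone in
the contamination rate.

## Stage model and contrasts

Daily minima (or maxima) are modelled with a Gaussian linear mixed model:
stage as an unordered fixed factor (reference: non-pregnant), a random
intercept per female, REML estimation. Days are the unit of observation;
the random intercept absorbs the ~1.5 °C between-female spread but no
within-female autocorrelation is modelled (consecutive days share stage, so
residual AR would mildly understate SEs; contrasts themselves are
unbiased — parameter-recovery tests bound the bias under the generator at
< 0.05 °C).

Pairwise contrasts use the estimated marginal stage means with the Tukey
studentized-range adjustment (the default of the usual marginal-means
tooling; Bonferroni and unadjusted are available), α = 0.05. Degrees of
freedom are a containment-style approximation, `N − k − (g − 1)`; with tens
of days per female this is near-equivalent to a Satterthwaite calculation
and verified to hold the family-wise error at the nominal level in null
simulation (200 cohorts). The compact letter display uses insert-and-absorb,
which guarantees two stages share a letter iff their adjusted difference is
non-significant. Degenerate inputs: a response that stage dummies fit
exactly (zero residual variance) is returned as the stage means directly;
balanced designs reproduce OLS fixed effects exactly.

## Event detectors

All detectors are deterministic and self-calibrated per animal from
pre-pairing days only (male introduction disrupts the rhythm):

* **Warm threshold** = midpoint of the rest-phase and active-phase medians
  of the pre-pairing 20-min binned minima — insensitive to the baseline
  spread between females.
* **Warm-phase offset** of a day = length (h) of the contiguous run of
  20-min bins above the warm threshold scanning forward from lights-on.
  Contiguity matters: stages that raise rest temperature toward the
  threshold otherwise produce isolated warm bins deep in the rest phase
  that inflate a "last warm bin" statistic. Missing bins end the run; days
  under 50% bin coverage are undefined.
* **Copulation** = earliest post-pairing day with offset ≥ 3 h.
* **Pregnancy course** relative to a copulation call, against the *median*
  pre-pairing daily minimum (median, because estrus days inflate a mean):
  pregnancy = ≥5 days of ≥0.2 °C elevation within the first reversion+5
  days *and* mean elevation ≥0.2 °C in the week after the 7-day reversion
  window; pseudo-pregnancy = ≥2 elevated days inside the reversion window
  without the late persistence; otherwise none; indeterminate when
  follow-up is too short.
* **Birth** = earliest day in expected-term ± 5 days with both an offset
  ≥ 3 h and the next five days' minima elevated ≥ 0.5 °C. Earliest (not
  best-scoring) because lactation keeps rest temperature near the warm
  threshold and later days can show spuriously long warm phases.
* **Cyclicity** = ≥2 peaks of prominence ≥ 0.2 °C in the pre-pairing daily
  minima at a median spacing of 3–6 days (≥5 usable days required).

Measured recovery at generator defaults (20 cohorts): copulation and birth
within ±1 day in 100% of pregnancies, pregnancy classified in 100%,
pseudo-pregnancy in ~92%, zero copulation false positives on effect-free
cohorts, cycling/non-cycling agreement ≥ 97%. These rates are conditional
on the generator's effect sizes matching the data; every threshold lives in
`DetectorParams` and is reported alongside each call.

## Morphometry

Zone areas are label pixel counts × (µm/px)² (mm²); per-site summaries take
the median across ≥3 sections (mean also emitted, since either summary is
defensible), and relative fractions divide by the summed medians. The
point-count estimator lays an `nx × ny` factorization of n points (400 →
20×20) with a shared random offset uniform over one grid cell (systematic
uniform random; a centred fixed grid is available for exact
reproducibility), classifies each point by the pixel under it (no
sub-pixel interpolation), and attaches binomial SEs √(p(1−p)/n). Tissue
and nuclei-clump fractions are pooled; absolute compartment areas are
fraction × zone area and conserve the zone area exactly. Cell counting
smooths the Euclidean distance transform (σ = 1 px), seeds a watershed at
its maxima (minimum separation 5 px) and discards objects < 20 px.

Synthetic sections: the low-mag mask is an elliptical disc whose interior
is rank-thresholded from one smoothed Gaussian field into three zones with
exactly the requested area fractions; the high-mag compartment mask is an
argmax mosaic over four independent smoothed fields whose per-class offsets
are iterated until realized fractions are within 0.5% of the request. The
mosaic (not nested level sets) is essential for validating sampling error:
level sets of a single field carry long-range indicator correlations that
make systematic-grid SEs deviate from the binomial formula, whereas the
mosaic decorrelates at the blob scale (σ = 4 px against a 25.6 px grid
spacing at 400 points on 512²), putting the estimator in the regime where
the SE is √(p(1−p)/n) to within 20%. At 1600 points the grid spacing
approaches the blob scale and systematic sampling beats the binomial rate —
expected stereological behaviour, asserted as such in the tests.

## Problem sizes and determinism

Validation uses 20 cohorts of 9 females (~55 simulated days, ~25,000 reads
per female) for recovery checks, 200 simulated null cohorts for family-wise
error, and 200 random grids for stereology calibration; the full suite and
the acceptance script each run in about a minute on one CPU. All randomness
flows through explicit `numpy` generators seeded from a single integer;
fixed seeds reproduce outputs bit-for-bit.
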