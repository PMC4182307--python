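# runwheel

Analysis pipeline for **home-cage running-wheel phenotyping** of mouse
models of progressive motor disease (built around the SOD1^G93A ALS model).
Voluntary nocturnal wheel running, recorded by a magnet-and-reed-switch
odometer, yields a daily, low-stress readout of motor function. A sustained
**20% decline from baseline** in daily running is an early, low-variance
endpoint: it appears weeks before overt neurological signs, and its low
coefficient of variation lets preclinical studies shrink from 14 mice per
group (rotarod) to 4–5.

`runwheel` implements that methodology end to end as a tested, reusable
library plus CLI:

- **`runwheel.sim`** — synthetic cohorts: rotation-event streams (Poisson
  bouts in the dark phase, log-normal durations, revolution intervals =
  circumference/speed with jitter), piecewise log-linear disease
  trajectories with per-animal changepoints, plus weekly rotarod, weight,
  clinical-score and survival series. Presets `wildtype` (ramp to peak
  ~day 31, slow drift, plateau means 15.07 km/day and 5.06 h/day) and
  `sod1` (peak ~day 40, plateau from day 60, second decline from ~day 100,
  cessation by ~130, maximum speed preserved at 2.8–3.5 km/h until ~120).
- **`runwheel.odometer`** — daily metrics from revolution timestamps:
  distance = revolutions × circumference (0.378 m); running time from bouts
  segmented with a **maximum inter-revolution gap of 5 s** (inclusive);
  average speed = distance/time per 24 h; maximum speed from a 5-revolution
  rolling-median-smoothed instantaneous speed. Day-level censoring (jammed
  wheel, unreset odometer, detached switch, water leak).
- **`runwheel.onset`** — per-animal onset: baseline = running peak of a
  7-day rolling mean over non-censored days; onset = first age at or below
  80% of baseline sustained for 3 evaluable days (1 confirmatory repeat for
  weekly rotarod vs the post-training baseline); clinical onset = first age
  with both enhanced tremor and defective hind-limb splay.
- **`runwheel.cohort`** — study summaries (n, mean, SD, CV = 100·SD/mean),
  between-study CV, Kaplan–Meier onset curves, log-rank, unpaired
  t/Mann–Whitney, Kruskal–Wallis with Dunn's post-hoc z tests.
- **`runwheel.power`** — exact two-sample t-test power via the noncentral t
  (df = 2n−2, noncentrality (δ/σ)·√(n/2)), minimum group-size search, and a
  Monte-Carlo oracle.
- **`runwheel.reference`** — published placebo-cohort onset summaries (seven
  studies plus the pooled row) used by the reproducibility and power
  calculations.

## Worked example

Simulate a diseased cohort of 15, reduce events to daily metrics, detect
onsets and summarize — then size a follow-up study:

```sh
$ runwheel run --preset sod1 --n-animals 15 --seed 7 --outdir demo
INFO runwheel: simulate: 15 animals, 1581 daily records (4 censored)
INFO runwheel: onset: 90 results, 0 censored
INFO runwheel: cohort: 5 study/metric summaries
INFO runwheel: power: min group size 4 (delta=10, sd=3.93)

$ cat demo/summaries.csv
study_id,n,metric,mean_onset,sd_onset,cv_percent
study-1,15,avg_speed,48.2,2.42605,5.0333
study-1,15,clinical,78.4,8.44985,10.7779
study-1,15,distance,44.6,2.47271,5.54419
study-1,15,rotarod,66.7333,8.72162,13.0694
study-1,15,time,46.3333,2.94392,6.35378

$ runwheel power --delta 10 --sd 3.93 --n 4
power = 0.8482
$ runwheel power --delta 10 --sd 3.93 --target-power 0.8
min n per group = 4
```

Reading the output: the simulated cohort shows a 20% decline in distance
run at a mean age of 44.6 d (CV 5.5%), well before clinical onset at
78.4 d; with the pooled between-animal SD of 3.93 d, groups of 4 give 84.8%
power to detect a 10-day shift in that onset age.

`demo/manifest.json` records the seed and SHA-256 digests of every output;
rerunning with the same seed reproduces the files bit for bit.

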