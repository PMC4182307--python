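# Methods

## The measurement model

A home-cage running wheel (circumference 0.378 m) closes a reed switch once
per revolution; an odometer accumulates revolutions over a 24 h window read
each morning. Four daily metrics summarize an animal-day:

- **distance** (km) = revolutions × circumference;
- **time** (h) = summed span of *bouts*, where consecutive revolutions
  separated by gaps ≤ 5 s belong to one bout (the 5 s figure is inclusive:
  a gap of exactly 5 s is continuous). A bout's span is last − first
  timestamp, so a single-revolution bout contributes distance but no time
  — the same convention a cycle odometer uses for "moving time";
- **average speed** (km/h) = distance / time for the day, *missing* (not 0)
  on days with no accrued time, so zero-activity days cannot fake declines;
- **maximum speed** (km/h): instantaneous speed per revolution is
  circumference / inter-revolution interval, smoothed by a 5-revolution
  rolling median confined to one bout, then maximized over the day. The
  median window rejects single-interval jitter. Because distance counts n
  revolutions while time counts n−1 intervals, the smoothed maximum can dip
  ~1% below the day's average on sparse days; the reported maximum is
  floored at the average, which is a hard lower bound for the true maximum.
  The odometer hardware's own maximum-speed algorithm is unknown; this
  estimator is a declared convention of the package.

Days invalidated by hardware faults (jammed wheel, odometer not reset,
detached reed switch, water leak, other) are censored: metric fields are
cleared and every downstream aggregation skips them.

## Onset: first sustained 20% decline

Per animal and metric, the baseline is the **running peak of a 7-day
rolling mean** over non-censored days (window and mode configurable; a
rolling mean keeps single-day spikes from setting an unreachable
reference). Onset is the first day after the baseline day whose value is
≤ 0.8 × baseline and stays there for 3 consecutive evaluable days; the
crossing day itself is reported. Censored days are skipped, never
interpolated. Weekly rotarod (best-of-two latency, 5 s floor, 300 s
ceiling) uses the animal's first post-training test as baseline and a
single confirmatory repeat at the next test, since weekly data are already
smoothed by best-of-two. Clinical onset is the first age with both
enhanced tremor and defective hind-limb splay; peak-weight age breaks ties
toward the earliest age. The persistence and window defaults are package
conventions — the 20% rule itself does not prescribe them — and both are
exposed as parameters.

## The synthetic cohort generator

The generator exists so that every downstream stage is testable without
animal data. It emulates the *statistical shape* of voluntary running over
a murine ALS-like disease course, not its physiology.

**Event level.** A night holds a Poisson number of bouts placed
sequentially in the 12 h dark phase (the recording day is morning-aligned,
so the dark phase is the second half of the window). Bout durations are
log-normal (CV 0.6). Bout speeds are a two-component mixture: a
*cruising* component (log-normal around a typical speed that tracks
disease) and a 15% *sprint* component whose speed is preserved until late
disease. The mixture is what dissociates average speed (declines from
soon after peak) from maximum speed (stable at ~2.8–3.5 km/h until
~day 120), as observed in this model. Revolution intervals within a bout
are circumference/speed with 3% log-normal jitter. No intra-day bout
statistics are published for this preparation, so the bout model is a
stand-in; its parameters are calibration knobs, not biological claims.

**Trajectory level.** Per-metric capacity (bout count; cruising speed;
sprint speed) is piecewise log-linear between per-animal changepoints
drawn from truncated normals: juvenile ramp → peak (wild-type ~31 ± 2 d,
diseased ~40 ± 3 d) → first decline → plateau (peak + 20 d) → second
decline (from ~100 d) → cessation (well before the humane endpoint), with
capacity 0 at and after cessation. Wild-type animals instead drift down
slowly (0.2%/day on bout count) with speeds stable. A log-normal
between-animal activity scale (CV 11.5% healthy, 18% diseased) reproduces
the published cohort spreads.

**Calibration.** Wild-type bout rate and cruising speed are closed-form
functions of the published plateau targets (post-peak means 15.07 km/day,
5.06 h/day; these imply a mean speed of 2.978 km/h, which the preset uses
exactly). The diseased first-decline rates (bout count 0.062/day, cruising
speed 0.0414/day) were calibrated end-to-end — events → daily metrics →
default onset detection — against the published mean onset ages; the three
published onsets (44.3/45.5/47.1 d for distance/time/average speed) are
mutually inconsistent under any two-channel multiplicative model, so the
distance onset is anchored and the ordering preserved (simulated means
~44.1/45.7/47.1 d at n = 100). Rotarod decline-start means (47.4 d
no-wheel, 58.5 d with wheel, ~0.062/day log decline) are likewise
calibrated through the weekly best-of-two protocol, whose grid
quantization and confirmatory repeat add ~7–8 d between latent decline and
detected onset, reproducing detected means of ~55.1 and ~65.8 d.
Censoring is an independent per-day Bernoulli at a rate of 0.23 expected
censored days per animal over the window.

**Reproducibility.** The master seed spawns one `SeedSequence` substream
per animal, and each animal splits its stream into per-trait substreams
plus a day-level stream. Cohorts are therefore bit-reproducible, animals
can be appended without perturbing existing ones, and no latent trait sits
at a fixed draw position shared across animals (a fixed position lets a
single unlucky pattern in the underlying streams bias one trait across a
whole cohort).

**What the generator does not emulate** — and hence what passing tests do
not show about real animals: litter and cage effects, seasonal or
experimenter variation, correlated multi-day activity weather, learning on
the rotarod beyond best-of-two, sex differences (the reference protocol
used females only), or any treatment effect mechanism. Calibration tests
validate the pipeline's mechanics at realistic signal/noise, not biology.

## Cohort statistics

Study summaries use the sample SD (n−1) and CV = 100·SD/mean over animals
with observed onsets only; censored animals enter Kaplan–Meier onset
curves as censoring marks instead. Between-study CV is the sample SD of
study means over their mean. The group comparisons are the field's
standard ones: Mantel–Cox log-rank (lifelines), unpaired pooled-variance t
(Welch by flag), exact Mann–Whitney for small samples, tie-corrected
Kruskal–Wallis, and Dunn's post-hoc pairwise z tests with Bonferroni
family-wise adjustment across the three comparisons (the family-wise
scheme for "Dunn's multiple comparisons" is not standardized; Bonferroni
is the conservative choice). Display rounding is one decimal; all internal
computation is full precision.

## Power

Exact power for the equal-n two-sample t test: with true difference δ and
common SD σ, the statistic is noncentral t with df = 2n − 2 and
noncentrality (δ/σ)√(n/2); power is the mass beyond the central-t critical
value (both tails when two-sided, the default — one- vs two-sided is not
recorded for the original calculations, and both reproduce the published
group sizes). `min_group_size` scans n upward (power is monotone in n).
The Monte-Carlo oracle simulates normal cohorts and applies the
pooled-variance test directly; analytic and simulated power agree within
binomial error across the tested grid. With the pooled reference SDs,
δ = 10 d gives n = 4 per group at SD 3.93 (power 0.848) and n = 5 at
SD 4.84 and 4.21; at the rotarod SD of 9.1 d, power at n = 14 is 0.799,
so the strict 0.80 search returns 15.

## Numerical and scale choices

Problem sizes follow the reference protocol: cohorts of 15, daily
recording over ~130 days, weekly rotarod/weight/scores. Calibration tests
accept a cohort statistic within 2 standard errors of its target;
Monte-Carlo checks use 2–3 binomial SEs. The between-metric Dunn
comparison at the calibrated effect (≈3 d shift, SD ≈ 3, n = 15,
Bonferroni) has true power ≈ 0.54 by an independent Gaussian-level oracle,
so the corresponding test asserts detection in most — not ≥80% of —
replicates. Ages are integer days of life; timestamps are seconds within
the window; all unit conversions live in the odometer module.
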