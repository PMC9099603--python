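# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `sfskit`, in the order data flow through the pipeline.

## The measurement problem

A social foraging system (SFS) station couples an operant key, a retractable
food hopper, an RFID aerial, and a perch balance sampled at 6 Hz. Birds in a
closed economy earn all food through the key (fixed ratio 1: one peck → 5 s
hopper access → 2 s inter-trial interval), so the raw data are four event
streams per station: balance readings, chip reads, pecks, and a daily
hopper/spill ledger. The analysis task is to turn these into per-bird-day
quantities — stable masses, diurnal trajectories, dawn/noon/dusk masses,
daily gain and nightly loss, reinforcement counts — and then into
population inference about mass regulation.

## Stable-mass detection

A stable mass is emitted at the **first** window of 5 consecutive readings,
all strictly above 50 g, whose spread (max − min) is at most 5 g; the event
time is the window's last reading and the event mass is the window mean.
After an emission, detection is locked out until a reading strictly below
10 g shows the perch was vacated. Numerical choices:

* **Window mean** as the event mass. The alternatives (first or last
  reading of the window) are noisier; the choice is configurable and only
  shifts event masses by fractions of the reading noise.
* Strict inequalities for the 50 g and 10 g thresholds; the 5 g spread is
  inclusive.
* Detection state never crosses stations or days.
* The implementation is vectorised (sliding windows + lockout scan) and is
  verified in tests against a deliberately naive reading-by-reading oracle
  on randomised streams; the two must agree exactly.

Automatic re-zeroing of the balances is assumed to have been applied
upstream by the feeder firmware; no drift correction is attempted.

Attribution assigns each event to the bird whose chip was read most
recently on that station within a staleness window, default **5 s** — long
enough to bridge the ~1 s read cadence with occasional missed reads, short
enough that the previous occupant of a perch cannot inherit an event after
a changeover (visits are separated by at least the reset excursion).
Events with no qualifying read are dropped and counted, never guessed.
Masses above **120 g** (beyond any plausible starling) are then removed and
counted.

## Diurnal trajectory model

Per bird-day, mass is an OLS polynomial in time of day, centred at dawn
(u = t − 8 h) to reduce collinearity between powers. The fit is two-pass:
a cubic screening fit, removal of points more than 10 g from it
(biologically implausible given daily gains of ~4–8 g), and exactly one
cubic refit. Both passes use degree 3. A bird-day needs ≥ 10 masses before
the first pass and again after exclusions, and a non-degenerate time design.
Degree comparison uses the Gaussian profile-likelihood AIC,
n·ln(RSS/n) + 2k with k = degree + 2 (coefficients plus error variance);
AICc is deliberately not used, and ties break toward the lower degree.
RSS is floored at a tiny constant so that exact fits (RSS = 0 at several
degrees) still tie-break correctly.

Point estimates at dawn (0800), noon (1200) and dusk (1600) are guarded:
an estimate is only reported when a **retained** mass lies within 1 h of
the target time, so the polynomial never extrapolates into an empty part of
the day. (Whether the guard should consult pre-exclusion masses is
ambiguous; retained masses are the conservative choice and the difference
affects only bird-days whose entire evening data were excluded as
outliers.) Daily gain is dusk − dawn within a day; nightly loss is the
previous calendar day's dusk minus today's dawn, and is reported as missing
whenever either endpoint is missing — losses are never bridged across a
gap day.

## Foraging effort and consumption

Under FR-1, pecks and reinforcements coincide, so per-bird-day effort is a
count of attributed pecks; rates use the 9.25 h session (0800–1715).
Hourly rates use left-closed hour bins from 0800 with the final partial bin
(1700–1715) scaled by its 0.25 h width. Station capacity assumes a fixed
1 s peck latency after key onset: ⌊33300 s / (1 + 5 + 2) s⌋ = 4162
reinforcements per station per day (floor, not rounding). Consumption is
hopper start − end − spill per aviary-day, divided by group size; negative
values are flagged as QC errors, not clipped. Training acquisition is
summarised as trials-with-a-peck per bird-session, with aviary progression
requiring every bird to reach 3 pecked trials.

## Inference

**Reliability.** ICC(2,1)/ICC(A,1): two-way random effects, single
measurement, absolute agreement, computed from the ANOVA mean squares of
the birds × days matrix (listwise-complete rows), with the F-based 95% CI.
The implementation is cross-checked against `pingouin.intraclass_corr` in
tests. In the no-day-effect limit the estimator converges to
σ²_bird/(σ²_bird + σ²_resid), which the tests verify at a 0.85:0.15
variance split.

**Mixed models.** Random-intercept Gaussian LMMs fitted by REML via
statsmodels `MixedLM`; sex enters as a fixed effect with female as the
reference level. Satterthwaite denominator degrees of freedom are computed
in-package from the analytic marginal covariance Σ = σ²ₑI + σ²_b ZZ′: for a
contrast c, df = 2(c′Cc)²/(g′O⁻¹g) with C the GLS coefficient covariance,
g the gradient of c′Cc in (σ²_b, σ²ₑ), and O the **observed** REML
information (the convention lmerTest uses; tests show agreement with
lmerTest to ~4 decimals in betas, SEs, dfs and p-values). Dense linear
algebra keeps this exact and is ample for cohort-scale data. Singular fits
are floored at zero variance with a warning. An aviary random intercept is
deliberately omitted from the default models (it explains essentially no
variance in this design, with only two aviaries); the `group` argument can
be repointed if needed.

**Within/between decomposition.** The predictor is split exactly into a
within-bird component (observation minus bird mean) and a between-bird
component (bird mean). Model 1 uses the raw predictor; model 2 the two
components; model 3 the raw predictor plus the between component, whose
coefficient equals the between − within difference. Because models 2 and 3
span the same column space, their REML optima are linked by exact algebraic
identities, which the fitting routine checks on every call and tests
enforce at 10⁻⁶. If all subject means coincide, the between component is
collinear with the intercept and is dropped with a warning.

## The synthetic-data generator

The generator's defaults emulate the reference study design: 12 birds
(6 M / 6 F) in two aviaries, one station per three birds, lights and
session 0800–1715, 6 Hz balances, FR-1 schedule, 11 days.

Per-bird latent parameters are drawn once per cohort:

| parameter | default | rationale |
|---|---|---|
| dawn mass | U(71.1, 91.4) g | observed cohort extremes |
| daily gain | U(3.6, 8.3) g | observed cohort extremes |
| trajectory shape | hump U(0.1, 1.5) g; inflection U(−0.6, 0.6) g | see below |
| visit rate | dawn U(9, 16)/h → dusk U(2.5, 6)/h, linear decline | declining foraging over the day; ~40–120 visits/day |
| reinforcement target | U(129, 568)/day | observed per-bird means |
| balance noise | 1.5 g i.i.d. per reading | reading-level jitter of a moving bird |
| posture offset | N(0, 1.0 g) per visit | see below |
| bad-perch rate | 1% of readings → U(15, 45) g | exercises the stability filter |

The latent trajectory is the linear dawn→dusk gain plus two
endpoint-anchored bumps: a concave midday hump (deceleration — birds
forage hardest early) and a normalised inflection term allowing a late
slow-down or pre-dusk uptick. Amplitudes are in grams so they are directly
comparable to noise; the chosen ranges make per-bird-day AIC degree
selection produce a realistic mix of linear/quadratic/cubic best fits with
cubic as the modal outcome, as observed in real cohorts.

Visits follow an inhomogeneous Poisson process (thinning) with the linearly
declining intensity; durations are lognormal (σ = 0.9) with the per-bird
median set so that the FR-1 peck cycles fitting inside the visits
approximately meet the bird's reinforcement target (a fixed ~8 s median
cannot reach realistic totals of several hundred reinforcements/day at
realistic visit counts, since one 8 s cycle fits per visit). Overlapping
visits to one perch drop the later arrival, so a perch never holds two
birds; the peck generator carries each station's feed + ITI lockout across
visits, so two reinforcements on one station are never closer than 8 s.
The 6 Hz balance stream is emitted during visits plus short near-zero
bursts (< 10 g) around them — enough to exercise the detector's reset rule
without materialising ~200k idle readings per station-day. RFID reads are
emitted at ~1 Hz during visits, alternating randomly between the bird's two
chips. The hopper ledger debits 0.095 g per reinforcement (≈ 25 g per bird
per day at ~260 reinforcements) plus a small uniform spill.

**What the posture offset is for.** With only i.i.d. reading noise, the
five-reading window mean would have ~0.7 g error and daily fits would reach
R̄² ≈ 0.88 — far cleaner than real perch data, where posture, crop content
and stance shift the whole visit's readings together. The per-visit offset
(σ = 1.0 g) reproduces the realistic regime: mean daily-fit R² ≈ 0.7,
dusk-mass estimates still within 1 g of latent truth on ≈ 98% of bird-days,
but gain/loss (differences of two estimates, hence doubled error) noticeably
less reliable — the same pattern seen in real cohorts, where gain and loss
reliability collapses even though the underlying masses are highly
repeatable. The end-to-end recovery checks in the acceptance suite run
under the plain i.i.d.-noise condition (posture offset 0, noise 1.5 g),
which is the condition those checks specify; the realism features stay on
everywhere else.

**What the generator does not emulate:** station changeovers by one bird
within an aviary (each simulated bird has a home station), scrounging and
displacement at the hopper, dominance structure, balance drift and
re-zeroing, missed or corrupted RFID reads, and day-to-day drift in latent
dawn mass (latent trajectories repeat across days, which is also why mean
gain ≈ mean loss holds exactly in expectation). Passing recovery tests
therefore demonstrates the pipeline's correctness under a realistic noise
and visit model, not robustness to every field failure mode.

## Problem sizes and runtime

The default simulated cohort (12 birds × 11 days, ~1.6 M balance readings)
runs the full pipeline in well under a minute. The acceptance script uses
that cohort size for end-to-end recovery, 1000 random streams of 50–400
readings for detector/oracle equivalence, and 200 summary-level cohorts
(12 × 11 bird-days generated directly from the latent mixed model at the
reference scales) for slope-recovery coverage, which keeps the whole script
around half a minute on one CPU.

## Known limitations

* Food consumption is only measurable at aviary level; per-bird intake is
  approximated by reinforcement counts.
* The Satterthwaite machinery covers the single-random-intercept models the
  pipeline uses; nested or crossed random effects would need the fitting
  backend's own inference.
* The stable-mass detector assumes the stream is time-ordered and that
  balance zeroing has been handled upstream.
* Report-table rounding is one decimal for masses (two for correlations,
  four for slopes); internal computations keep full precision.
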