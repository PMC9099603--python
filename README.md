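# sfskit

Analysis pipeline for **social foraging system (SFS)** event logs: automated
smart feeders that let group-housed birds (European starlings in the
reference design) earn all of their food by pecking an illuminated key,
while an RFID aerial identifies the bird on the perch and an electronic
balance under the perch streams its mass at 6 Hz. The scientific aim is to
measure, without catching and handling birds, how foraging effort and body
mass are regulated: each bird's diurnal mass-gain trajectory, its dawn and
dusk masses, its daily gain and overnight loss, and whether day-to-day
(within-bird) or stable (between-bird) variation in foraging effort explains
variation in dusk mass.

`sfskit` is aimed at behavioural ecologists running (or simulating) such
closed-economy experiments. It covers the full chain from raw event streams
to inference:

1. **Stable-mass detection** — a streaming filter that records a mass at the
   first run of five consecutive balance readings > 50 g spanning ≤ 5 g,
   then locks out until the balance drops below 10 g (the bird left the
   perch). Masses > 120 g are discarded as measurement error.
2. **Attribution** — each stable mass is assigned to the bird whose RFID
   chip was read most recently on that station (each bird wears two chips).
3. **Trajectory fitting** — per bird-day, mass *m* is modelled as a cubic in
   time of day *t* (hours, centred at dawn):
   *m(t) = β₀ + β₁u + β₂u² + β₃u³*, *u = t − 8*, by OLS with a two-pass
   outlier rule (fit, drop points > 10 g from the fit, refit once), needing
   ≥ 10 masses. Degree 1/2/3 can be compared per bird-day by
   AIC = *n* ln(RSS/*n*) + 2*k*. Dawn (0800), noon (1200) and dusk (1600)
   masses are read off the refit, but only if a retained mass lies within
   1 h (no extrapolation). Daily gain = dusk − dawn; nightly loss =
   previous dusk − dawn.
4. **Foraging effort** — under the FR-1 closed economy every peck earns one
   5 s reinforcement, so effort is the attributed peck log; the theoretical
   station capacity is ⌊session/(latency + feed + ITI)⌋ = 4162/day.
5. **Inference** — between-day reliability via ICC(2,1) (two-way random
   effects, single measurement, absolute agreement) with F-based 95% CI;
   random-intercept linear mixed models (REML, Satterthwaite df, sex as
   fixed effect); and the van de Pol & Wright within-/between-subject
   decomposition: regress dusk mass on the within-bird component
   (reinforcements − bird mean) and between-bird component (bird mean), plus
   a third model whose between coefficient tests the difference of the two.

A fully specified simulator (`sfskit.synthetic_data`) generates raw logs
from known per-bird ground truth (latent cubic trajectories, inhomogeneous
Poisson visits declining over the day, balance noise and bad-perch
contamination, the FR-1 schedule and both training schedules), so every
stage is validated by parameter recovery.

## Worked example

Simulate a 12-bird, 11-day experiment and run the full pipeline:

```bash
sfskit all --seed 42 --outdir sfs_run
```

which writes the stage CSVs (`balance.csv`, `stable_masses.csv`,
`bird_days.csv`, `per_bird.csv`, …), a `stats.json`, a run log with every
threshold, and prints the cohort summary:

```json
{
  "n_birds": 12,
  "reinforcements_per_day_mean": 276.545,
  "daily_gain_g_mean": 6.102,
  "nightly_loss_g_mean": 6.09,
  "noon_mass_g_mean": 86.622,
  "r_dawn_dusk": 0.987,
  "r_gain_loss": 0.998
}
```

(abridged). Reading it: the simulated birds averaged ~277 reinforcements
per day, gained 6.10 g between dawn and dusk, and lost an equal 6.09 g
overnight — mass is in steady state; per-bird mean dawn and dusk masses are
almost perfectly correlated (r = 0.99), while gain and loss mirror each
other (r = 1.00). The first rows of `per_bird.csv`:

```
bird_id sex  reinf_per_day_mean  dawn_mass_mean  dusk_mass_mean  daily_gain_mean  nightly_loss_mean
    B01   M               382.6            86.8            92.5              5.7                5.8
    B02   F               319.9            80.3            85.7              5.3                5.4
    B03   M               219.9            88.0            94.4              6.4                6.4
```

The same stages are available as library functions
(`stable_mass.detect_stable_masses`, `trajectory.fit_daily_trajectory`,
`stats.fit_three_model_sequence`, …) for use on real feeder exports in the
same CSV layout.

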