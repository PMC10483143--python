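# soundarena

A software implementation of the **sound arena**, a closed-loop auditory
place-preference/avoidance test for mice, together with the full trajectory
analysis and statistics pipeline used to score it and an agent-based
simulator that makes every stage testable without animal data.

## The assay

A mouse explores a square open field (44 × 44 cm, walls 30 cm) that is
divided by its midlines into four *virtual* quadrants. One quadrant role
(Q1) is silent; the other three (Q2–Q4) are each tied to a pure tone —
either 8/12/16 kHz at 50 dB SPL (audible condition) or 20/24/28 kHz at
70 dB SPL (ultrasound condition). The animal's centroid is tracked at
20 fps; whenever it occupies a tone quadrant, that quadrant's tone plays;
in Q1 nothing plays. A session is 5 min of silent habituation followed by
30 min of exposure. Which physical corner is silent (and which tone goes
where) is held constant within a wild-type/knockout pair and counterbalanced
across pairs. An animal that finds the tones aversive withdraws into the
silent quadrant — *auditory avoidance* — which the pipeline quantifies as:

- **occupancy**: per-role time fraction per phase (baseline ≈ 25 % each);
- **preference index**: per role, 100·(exposure fraction − habituation
  fraction), percentage points; components sum to 0;
- **time course**: occupancy in 5-min bins (1 habituation + 6 exposure);
- **AUC**: trapezoidal area under a role's exposure time course against bin
  midpoints, in fraction·minutes (constant 25 % occupancy → 6.25);
- **locomotion**: total and per-role path length with an artifact speed
  filter; plus position heat maps.

Cohort statistics follow the assay's standard battery: two-tailed Student's
*t* (pooled variance), one-way ANOVA with Tukey HSD, and two-way
repeated-measures ANOVA (with optional Greenhouse–Geisser correction), all
reported as mean ± 95 % CI.

## Worked example

Simulate a small paired cohort (silence-seeking "ko" profile vs unbiased
"wt" profile), analyze every session, and run the cohort statistics:

```bash
soundarena demo --n 5 --seed 7 --out demo/
```

`demo/stats.json` then contains (seed 7):

- WT: quadrant ANOVA *F*(3,16) = 2.758, *p* = 0.076 — no quadrant
  preference; silent-vs-tone-mean *t*(8) = −1.199, *p* = 0.265.
- KO: quadrant ANOVA *F*(3,16) = 41.134, *p* < 0.0001; silent-vs-tone-mean
  *t*(8) = 10.893, *p* < 0.0001 — strong preference for silence.
- Mean exposure silent-quadrant occupancy: WT 23.9 %, KO 42.8 %.

Single sessions replay and analyze the same way:

```bash
soundarena replay  --config demo/KO01.yaml --traj demo/KO01.csv --out events.csv
soundarena analyze --config demo/KO01.yaml --traj demo/KO01.csv --out KO01.json
# exposure occupancy %: Q1=46.9, Q2=12.8, Q3=21.1, Q4=19.2
```

The replay writes the audited tone-command log (one row per debounced
quadrant transition); the analysis JSON holds occupancy, preference indices
(here Q1 +20.4 points), per-role AUC, distance and the heat-map mass.

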