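# snapmech

Biomechanics of asymmetric mandible snaps, as a tested, reusable pipeline:

- **morphometry** — centre of mass, inertia-adjustment constant K
  (`I_A = K·M_A·L_A²`, K ∈ [1/64, 49/64]) and cylinder whole-body inertia
  from subsection masses and lengths.
- **snap_kinematics** — tip velocity, mean angular acceleration, snap force
  and snap energy from ultrahigh-speed angular measurements; peak extraction
  from angular-velocity series.
- **ball_strike** — energy-conservation inversion of post-impact ball and
  termite motion into snap energy, tip velocity and impact force; strike-angle
  precision summary with a Shapiro–Wilk normality test.
- **track_processing** — calibrated speeds, rotation rates and direction
  angles from digitized pixel trajectories (y-down image convention handled).
- **defence_assay** — attack rate and hit/kill probabilities from pooled
  fight-trial counts; pairwise two-sided Fisher exact tests with Bonferroni
  correction and compact letter displays.
- **synthetic_data** — forward simulation of every input table with known
  ground truth (deterministic under a fixed seed; PCG64 streams per table).
- **cli / report** — subcommands tying the stages into a cohort report with
  provenance (seeds, file hashes) and unit-audited reporting tables.

Internal computation is strict SI; reporting converts through named unit
converters (μg, mg, mm, μs, μJ, mN, ×10⁴ rad/s, …) with round-half-up to
one decimal.

## CLI

```sh
# generate a full set of synthetic input tables (with _truth side-cars)
snapmech simulate --seed 1 --out-dir data/

# stage-by-stage
snapmech morph   --input data/morphometry.csv
snapmech snap    --morph data/morphometry.csv --events data/snap_events.csv
snapmech strike  --morph data/morphometry.csv --events data/ball_strike.csv
snapmech defence --input data/defence.csv

# full pipeline from a YAML config
cat > config.yaml <<EOF
simulate:
  seed: 1
  n_individuals: 17
  n_events: 92
EOF
snapmech report --config config.yaml --out-dir out/
```

`report` writes `report.json`, `report.txt`, `events.csv` and `defence.csv`.
A config may instead point at existing CSVs:

```yaml
inputs:
  morphometry: data/morphometry.csv
  snap_events: data/snap_events.csv
  ball_strike: data/ball_strike.csv
  defence: data/defence.csv
```

## Input formats

All inputs are plain CSV with headers (units encoded in column names):

| table | columns |
| --- | --- |
| morphometry | `individual_id, m_t_mg, l_t_mm, m_a1_ug, m_a2_ug, l_a_mm` |
| snap events | `individual_id, omega_a_rad_s[, t_a_us]` |
| ball strikes | `individual_id, event_id, v_b_m_s, v_t_m_s, omega_t_rad_s[, angle_deg, m_b_mg]` |
| tracks | `event_id, subject, frame, x_px, y_px` + YAML side-car (`frame_rate`, scale, `body_axis`) |
| defence trials | `species, trial_id, encounters, attacks, snaps, hits, kills[, immobilised, ants]` |
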