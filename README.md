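# runload

Synthetic wearable-IMU pipeline for biomechanical loading in distance
running. The package simulates tri-axial accelerometer streams (left tibia,
right tibia, sacrum; 120 Hz, units of g) for running bouts of a crossed
cohort design (3 elevations x 3 speed zones x 2 surfaces), segments them
into impact peaks, and computes bout-level loading metrics:

- **CAD** — cadence, from the union of left/right impact peaks (spm)
- **PTA** — mean peak tibial acceleration per leg and bilaterally (g)
- **LA / aLA** — signed/absolute lateral asymmetry:
  `LA = (aL - aR) / ((aL + aR)/2)`
- **RSh** — residual shock: sacral mean peak over the bilateral tibial
  mean; `1 - RSh` is the shock attenuation

On top of the metrics it provides speed-zone prescription from ventilatory
thresholds (`v1 = 0.9 vVT1`, `v2 = (vVT1 + vVT2)/2`, `v3 = vVT2`) with a
hypoxia-motivated altitude speed adjustment, and a three-way
repeated-measures ANOVA (Greenhouse–Geisser correction, Mauchly and
Shapiro–Wilk tests, Bonferroni post hoc comparisons, partial eta squared
and Cohen's d with Cohen rating bands) plus per-condition OLS slope
summaries.

## Layout

| module                | purpose                                            |
|-----------------------|----------------------------------------------------|
| `runload.synthetic`   | step trains, impact transients, bouts, cohorts     |
| `runload.gait`        | magnitude peak detection, margins, bout metrics    |
| `runload.prescription`| speed zones, hypoxia factor, altitude adjustment   |
| `runload.stats`       | rmANOVA, sphericity, effect sizes, post hoc, slopes|
| `runload.study`       | end-to-end study runner and summary tables         |
| `runload.reference`   | default group-summary calibration targets          |

## CLI

```sh
runload run-study --subjects 10 --seed 1 --out study_out
runload simulate --subjects 2 --seed 3 --duration 60 --out cohort_dir
runload analyse --streams cohort_dir/streams --out metrics.csv
runload stats --metrics metrics.csv --out stats_out
```

`run-study` writes the design table, per-bout metrics, 18-cell summary,
per-factor marginal summaries and, per metric, the rmANOVA effects table
and speed post hoc comparisons — all as versioned CSVs. Identical seeds
give byte-identical outputs.

## Notes

- With all noise sources zeroed, analysis recovers every programmed bout
  parameter exactly (to sample discretization); this embedding-fidelity
  property is enforced by the test suite.
- Streams are written as plain CSV (`t_s, ax_g, ay_g, az_g`) with a JSON
  sidecar of programmed parameters, so fixtures are reproducible from
  seeds alone.
- Per-bout peak averaging is per-step (not per-stride); the bilateral PTA
  is the mean of the two per-leg means.
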