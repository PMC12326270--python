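# mitoflight

Tools for asking whether the aerobic machinery of blood cells tells us
anything about whole-animal flight performance in small birds.

Nucleated avian red blood cells carry functional mitochondria, so a blood
sample — rather than a terminal muscle biopsy — can yield cellular
respiration phenotypes. `mitoflight` implements the full trait-derivation
and linkage pipeline for such a study:

1. **Take-off kinematics** — from 3D videogrammetry coordinates of an escape
   take-off (x, y, z in metres at a known frame rate), compute
   backward-difference speed `v[n] = ‖r[n] − r[n−1]‖ · fps`, per-frame
   mechanical energy `E = ½mv² + mgz` (heights referenced to the onset
   frame), and mean take-off energy expenditure over a 10-frame window — the
   anaerobic performance trait.
2. **High-resolution respirometry** — from a closed-chamber O2 concentration
   trace with titration events (pyruvate → oligomycin → step-titrated CCCP →
   antimycin A), estimate the respiration states ROUTINE, LEAK, ETS
   (maximum across CCCP plateaus) and non-mitochondrial O2 consumption as
   windowed least-squares slopes, subtract the non-mitochondrial flux,
   rescale to pmol O2 s⁻¹ µl blood⁻¹, derive OXPHOS = ROUTINE − LEAK and the
   two flux control ratios
   `E = 1 − LEAK/ROUTINE` (OXPHOS coupling efficiency) and
   `FCR = 1 − ROUTINE/ETS` (OXPHOS reserve capacity).
3. **Linkage statistics** — a response-independence pre-check (take-off
   energy vs flight endurance), a pairwise collinearity screen over the six
   mitochondrial predictors, one OLS model per predictor
   `response ~ mito + body mass + blood cell count` reporting `b ± SE`,
   partial `F = (b/SE)²`, `p`, model `R²`, standard residual diagnostics,
   and a leave-one-out refit dropping the most influential observation
   (Cook's distance > 4/n).
4. **Synthetic data** — generators for ballistic take-off tracks, titration
   traces and whole cohorts (n = 53 by default) whose endurance is linearly
   linked to ETS respiration and body mass, calibrated so the fitted ETS
   model has expected R² 0.29 and endurance is confined to the observed
   20–411 s range; the take-off arm is generated independently of all
   mitochondrial variables (a built-in null). Every downstream stage is
   testable without any field data.

## Worked example

Simulate a respirometry trace, derive its states and ratios, then fit the
headline endurance model on a synthetic cohort:

```bash
$ mitoflight simulate-trace --seed 3 --out-prefix s
$ mitoflight respiro s_trace.csv s_events.csv
{"sample_id": "s_trace", "routine_c": 1.1846, "leak_c": 0.2104,
 "oxphos_c": 0.9742, "ets_c": 2.2985,
 "coupling_efficiency": 0.8224, "reserve_capacity": 0.4846, "flags": []}
```

The corrected rates are per µl blood: this sample respires at 1.18 pmol O2
s⁻¹ µl⁻¹ under endogenous conditions, 82% of which drives ATP synthesis
(coupling efficiency 0.82), and it could raise respiration by 48% of its
uncoupled maximum (reserve capacity 0.48).

```bash
$ mitoflight simulate-cohort --n 53 --seed 7 --out cohort.csv
$ mitoflight run --cohort cohort.csv --out out --seed 7
mitoflight 0.1.0 run (seed 7)
cohort rows: 53
independence pre-check: slope p = 0.131
strong mito correlations (|r| > 0.7): 5 pair(s) -> separate models
models fitted: 12
  ...
  endurance_s ~ ets_c: b = 2.380 ± 1.154, F = 4.257, p = 0.044, R2 = 0.21, n = 53, influence: unchanged
  ...
```

One simulated cohort of 53 birds: endurance rises by 2.4 s per pmol O2 s⁻¹
µl⁻¹ of ETS capacity in this draw (the generating slope is 3.858; a single
cohort scatters around it), the model explains 21% of endurance variance,
and removing the most influential bird leaves the conclusion unchanged. The
library API mirrors the CLI: `simulate_cohort`, `takeoff_energy`,
`process_trace`, `fit_single_predictor_model`, `run_pipeline`, and friends.

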