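# ofzmpc

Offset-free impulsive zone model-predictive control for automated insulin
delivery, exercised end-to-end on a virtual diabetic-rat simulator.

The package implements the full stack around a linear five-compartment
glucose–insulin model:

- **`ofzmpc.core_model`** — the continuous compartment model
  (glycemia, two insulin delivery compartments, two carbohydrate
  compartments; six physiological parameters `p0`–`p5`) and its impulsive
  sampled form (`Ad = exp(A T)`, boluses entering as state jumps).
  Packaged fixtures carry the 13 per-subject parameter sets of the rat
  cohort.
- **`ofzmpc.observer`** — augmentation of the sampled model with an
  integrating disturbance state, observability verification, and a
  Kalman filter (time-varying or steady-state gain) estimating state and
  disturbance jointly from CGM samples, with dropout handling.
- **`ofzmpc.controller`** — the zone MPC: every 5 minutes a dense QP is
  solved over the bolus sequence and an artificial equilibrium
  `(xa, ua)`, with hard terminal and equilibrium equalities,
  disturbance-corrected predictions, hard `[0, 1]` U bolus bounds and a
  softly constrained `[90, 130]` mg/dL output zone; the first bolus is
  applied.  `ofzmpc.qp` provides the self-contained primal-dual
  interior-point solver it uses.
- **`ofzmpc.virtual_trial`** — virtual subjects: plant-model parameter
  mismatch, unannounced meal schedules (1–5 g every 2–4 h), CGM
  corruption (noise, outliers, dropouts), 72-hour closed-loop runs
  starting at 400 mg/dL (864 dose decisions).
- **`ofzmpc.identification`** — CGM cleaning (gap interpolation, Hampel
  outlier rejection, moving-median smoothing) and two-stage estimation
  of `p0, p1, p2, p4` (Latin-hypercube exploration with local polish in
  a 200-evaluation budget, then bounded trust-region least squares;
  `p3 = 9.5`, `p5 = 20.45` fixed).
- **`ofzmpc.metrics`** — time-in-range bands (<54, 54–70, 70–180,
  180–250, >250 mg/dL), episode counts, MedARD with percentile-bootstrap
  CI, precision-based sample size, Pearson correlations, and cohort
  mean/SD summaries; per-subject outcome fixtures ship as CSV.
- **`ofzmpc.trace_io` / `ofzmpc.config` / `ofzmpc.cli`** — flat-CSV
  trace I/O, YAML configuration with defaults and provenance, run
  manifests, and the command-line interface.

## Command line

```sh
# 72-hour virtual trial for cohort subject DR1 (or a p0..p5 YAML file)
ofzmpc simulate-trial --plant-params DR1 --seed 1 --out trace.csv

# same engine with a scenario override file
ofzmpc run-closed-loop --plant-params DR1 --scenario scenario.yaml --out trace.csv

# parameter identification from a trace window (minutes)
ofzmpc fit --trace trace.csv --window 0,300 --seed 1 --out params.json

# glycemic report (JSON plus a text band table)
ofzmpc report --trace trace.csv --out report.json

# re-run estimator + controller offline against recorded CGM
ofzmpc replay --trace trace.csv --plant-params DR1 --out replay.csv
```

Every command writes `<out>.manifest.json` with the config snapshot,
seed, package version, stage timings and file digests.  Configuration is
YAML; any subset of the documented defaults (see
`ofzmpc.config.DEFAULTS`) may be overridden, and unknown keys are
rejected.

## Notes on conventions

- Boluses are impulses: a dose of `D` U at a sampling instant enters the
  sampled recursion as `exp(A T) Bu D`.  The per-period equivalent of a
  continuous basal rate `u*` (U/min) is `D = T u*`.
- Meals of `g` grams are spread over their 5-minute interval as the rate
  `g / T` through the integrated input map, conserving carbohydrate mass.
- The controller never sees meals (`r = 0` in all predictions); the
  estimator's disturbance state absorbs them together with any other
  plant-model mismatch.
- The QP's zone constraint is softened by heavily weighted L1 slack, so
  large excursions are regulated rather than causing solver failure; on
  a numerical solver failure the controller injects nothing
  (`failed-safe`).
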