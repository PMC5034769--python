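# dynallo

Dynamic allometric scaling and biomass-fraction analysis for per-plant
leaf/stem/root dry-mass data.

Plant organ masses are classically related by power laws `Y = a X^b`
fitted on log-log axes. This package implements a pipeline built around
the question of whether the scaling exponent `b` is actually constant
across plant sizes:

- **dataio** — record/data-set model for per-plant (or per-harvest-mean)
  leaf, stem and root dry masses with taxonomy and functional-group
  labels; CSV/TSV reading, validation reports, declarative record filters.
- **synthetic_data** — generators with known ground truth: fixed-exponent
  power laws, smoothly size-varying exponents, size-dependent biomass
  fraction trajectories, and a bounded-random-fraction regime. All
  randomness flows from one explicit seed.
- **allometry** — standardized major axis (model 2) fits with the F-based
  slope confidence interval, OLS polynomial (model 1) fits up to cubic,
  BIC comparison (`n·ln(RSS/n) + k·ln(n)`), forward stepwise term
  selection, residual diagnostics (runs test, curvature correlation).
- **dynamic_slopes** — 50 equal-frequency size classes on log10 total
  mass, per-class medians, central-derivative-kernel triplet slopes,
  Loess smoothing, and a stratified record-level bootstrap giving a
  pointwise median curve with a 95% band; analytic polynomial-derivative
  slopes as a cross-check.
- **clasmometry** — leaf/stem/root mass fractions (LMF/SMF/RMF) and their
  Loess size trends with explained variance at record and class level.
- **percentiles** — size-corrected percentile ranks (`(rank−0.5)/n·100`,
  midranks for ties) of the fractions within each size class; species and
  family medians with t-tests against 50; Welch/ANOVA group contrasts
  with significance stars; sequential-SS variance partitioning.
- **demos** — the r²-inflation demonstration (log shoot vs log root stays
  at r² ≈ 0.94 even with root mass fraction uniform on [0.01, 0.99],
  with a closed-form oracle) and a minimal teleonomic growth model whose
  height-growth reward bends the realized scaling exponents.
- **pipeline** — one-config orchestration of all stages with
  deterministic per-stage sub-seeding and a machine-readable summary.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains one test per acceptance criterion.
Criteria that reproduce published numbers need the source per-plant
biomass table (not redistributable here) in the canonical column layout

```
record_id,species,family,growth_form,group_labels,leaf_mass_g,stem_mass_g,root_mass_g,source_id
```

placed at `data/table_s2.csv` or pointed to by `DYNALLO_TABLE_S2`.
Without the file those tests fail with an explanatory message; everything
else runs on synthetic data with known ground truth.

## CLI

```sh
dynallo simulate --regime fixed --n 5000 --seed 1 --out data.csv
dynallo validate data.csv
dynallo sma data.csv --y-organ leaf --x-organ stem
dynallo polyfit data.csv --y-organ stem --x-organ root
dynallo slopes data.csv --n-bins 50 --n-boot 20000 --seed 1 --out slopes.csv
dynallo fractions data.csv --outdir out/
dynallo percentiles data.csv --outdir out/
dynallo groups data.csv --group-a evergreen --group-b deciduous
dynallo r2demo --orders 2 --orders 6 --orders 10
dynallo toymodel --height-reward 0.5 --out traj.csv
dynallo run --config run.yaml
```

A run config is plain YAML, e.g.

```yaml
synth:
  regime: fixed
  n_records: 5000
  seed: 7
n_bins: 50
n_boot: 2000
seed: 42
outdir: out
```

## Notes on conventions

- Masses are stored in grams; all logs are base 10.
- The SMA slope CI uses the standard F-based construction
  `b·(√(B+1) ∓ √B)` with `B = F(1−α; 1, n−2)·(1−r²)/(n−2)` (the
  literature rarely states one; this choice is documented here).
- The BIC convention is internal and constant; only ΔBIC is interpreted.
- Loess = statsmodels `lowess` (tricube weights, local degree 1, no
  robustness iterations); the span is configurable everywhere.
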