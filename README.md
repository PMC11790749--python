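# biftwin

Bifactor twin modeling for MZ/DZ twin-pair item data.

The package implements the two bifactor twin-model families — the **common
pathway** model (latent phenotypic factors with ACE decompositions) and the
**independent pathway** model (separate A/C/E bifactor loading structures) —
with full-information maximum likelihood (FIML) over arbitrary missingness,
nested AE/CE/E submodels, likelihood-ratio tests, RMSEA/CFI/AIC/BIC model
comparison, and stratified pair bootstrap confidence intervals.  It also
provides the phenotypic bifactor workflow: Direct Schmid-Leiman estimation of
a general + group loading pattern from a correlation matrix, the
general-factor reliability indices (omega hierarchical, Hancock-Mueller H,
explained common variance), loading-adequacy summaries, and Cronbach's
alpha / omega total.  A twin-data simulator generates Conners-like ordinal
item data from either model family so every stage is testable without any
restricted cohort data.

## Library quick tour

```python
import biftwin as bt
from biftwin.configio import params_from_dict

structure = bt.conners_structure()          # 11 + 9 item bifactor layout

# phenotypic workflow
L = bt.load_published_loadings()            # packaged reference pattern
report = bt.general_factor_indices(L)       # omega_h, H, ECV with cutoffs
summary = bt.loading_summary(L)             # adequacy / dominance counts

# simulate and fit a twin model
params = params_from_dict({
    "family": "cp",
    "loadings": {"general": 0.55, "group": 0.4},
    "factor_ace": [0.63, 0.0, 0.77],
    "unique_ace": [0.3, 0.0, 0.6],
}, structure)
data = bt.simulate_twins(bt.SimulationConfig(n_MZ=1000, n_DZ=1000,
                                             params=params, seed=1))
spec = bt.ModelSpec(family="CP", components=frozenset("AE"),
                    structure=structure)
fit = bt.fit_model(data, spec, seed=1)
print(bt.aggregate_standardized_effects(fit)["A"]["shares"])
```

See `biftwin.simulate.SimulationConfig`, `biftwin.twin_sem.fit_model`,
`biftwin.fit_eval.bootstrap_ci` and `biftwin.workflow.run_pipeline` for the
programmatic API; every CLI verb is a thin wrapper over these.

## Command line

```bash
biftwin simulate --config sim.yaml --out pairs.csv
biftwin psychometrics --in pairs.csv --seed 1 --out psych.json
biftwin fit --in pairs.csv --family ip --components ace --out fit_ace.json
biftwin fit --in pairs.csv --family ip --components ae  --out fit_ae.json
biftwin compare --fits fit_ace.json --fits fit_ae.json --out table.json
biftwin indices --fit fit_ace.json --out indices.json
biftwin run --config run.yaml
```

Exit codes: 0 success, 2 validation failure, 3 convergence failure.

`biftwin run` writes `psychometrics.json`, `comparison.json`, `indices.json`
(plus TSV mirrors, and `bootstrap.json` when `bootstrap_B` is set) under the
configured output directory; every report embeds provenance (input hash,
config, seed, package version).

An example simulation config:

```yaml
n_MZ: 1800
n_DZ: 3300
seed: 7
ordinalize: true
missing_rate: 0.17
params:
  family: cp
  loadings: {general: 0.55, group: 0.4}
  factor_ace: [0.63, 0.0, 0.77]   # normalized to unit factor variance
  unique_ace: [0.3, 0.0, 0.6]
```

## Data format

Wide CSV, one row per twin pair:

```
pair_id,zygosity,age1,sex1,cohort1,age2,sex2,cohort2,i01_t1..i20_t1,i01_t2..i20_t2
```

Missing scores are empty cells.  Raw item scores are ordinal 0-3; covariates
are residualized out (OLS per item, pooling co-twins) before model fitting.

## Notes on conventions

- Additive-genetic cross-twin correlation: 1 (MZ) / 0.5 (DZ); shared
  environment 1; non-shared 0.
- Item scores are treated as continuous multivariate normal with means fixed
  at zero after residualization.
- omega hierarchical uses full column sums in its denominator; for
  model-implied (per-source) composites the denominator is the full
  model-implied composite variance across all sources.
- BIC / RMSEA sample-size convention: number of twin pairs contributing data
  (configurable via the `N` argument of `fit_statistics`).
- Likelihood-ratio tests at variance-component boundaries use the ordinary
  chi-square reference (no mixture correction), so they are conservative.
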