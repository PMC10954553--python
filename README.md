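# cndd

Estimation of stabilizing conspecific negative density dependence (CNDD)
in tree mortality from repeated forest-census data, with a synthetic
forest generator so the whole pipeline is testable without restricted
census data.

The pipeline follows a three-stage design:

1. **Species-site mortality models** — binomial GAMs with a complementary
   log-log link, penalized smooths of conspecific density, total density
   and DBH, a census random intercept and a log interval-length offset;
   smoothness is selected by REML. Rare species are pooled into per-site
   tree/shrub groups.
2. **Average marginal effects** — absolute (aAME) and relative (rAME)
   changes in annual mortality probability under a defined perturbation of
   conspecific density (one extra conspecific neighbour, DBH 2 cm, at
   1 m), with equilibrium / invasion / interquantile variants and
   simulation-based sampling variances (500 coefficient draws).
3. **Meta-regressions** — multilevel measurement-error models (site and
   species-in-site random intercepts plus known per-estimate variances,
   REML) of the transformed estimates against absolute latitude and log
   species abundance, plus per-site summaries (mean, interspecific s.d.,
   CV) and influence/randomization/spatial-autocorrelation robustness
   checks.

Local densities are kernel-weighted neighbour counts or basal areas
(exponential or exponential-normal distance decay, 30 m radius, separate
decay ranges for conspecific and total density) computed from the census
preceding each interval; the decay configuration can be selected by a
likelihood grid search.

## Layout

| module | role |
| --- | --- |
| `cndd.forest_data` | census ingestion, cleaning, focal-sapling observation tables |
| `cndd.synthetic` | multi-site synthetic forests with known ground-truth CNDD |
| `cndd.neighborhood` | decay kernels, conD/totD computation, grid search |
| `cndd.mortality` | penalized cloglog survival models (PIRLS + REML) |
| `cndd.marginal_effects` | aAME/rAME estimators and uncertainty |
| `cndd.meta` | multilevel meta-regressions, predictions, site summaries |
| `cndd.robustness` | randomizations, Cook's-distance filter, Moran's I screen, life-history confounders |
| `cndd.pipeline`, `cndd.cli` | config-driven orchestration and CLI |

## CLI

```sh
cndd validate --config config.yaml     # normalize + echo config
cndd simulate --config config.yaml --out run/   # synthetic censuses + truth
cndd run --config config.yaml --out run/        # full pipeline
cndd report run/                        # markdown summary
cndd predict --latitude 11.75 --intercept 0.004087 --b-latitude -0.000044
```

A config is YAML with defaults injected for every omitted key (smooth
basis dimension `k: 10`, `n_draws: 500`, mu grid `1:2:25`, radius 30 m,
centering at 11.75° latitude and 1 tree/ha, Cook's threshold 0.005); see
`cndd.pipeline.validate_config`.

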