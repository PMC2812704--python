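# carlm

Bayesian hierarchical linear models with intrinsic conditional
autoregressive (ICAR) spatial random effects, written for small-area
analysis of the **duration of untreated psychosis (DUP)** — the days
between onset of a first psychotic episode and first contact with mental
health services — but usable for any log-scale continuous outcome
observed on individuals nested in contiguous areas.

The package is aimed at psychiatric epidemiologists and spatial
biostatisticians who want to ask: *after adjusting for individual-level
confounders, does any meaningful share of the outcome's variance sit at
the neighbourhood level, and is it spatially patterned?*

## The model

For individual *j* in ward *i*, with T_ij = ln(DUP in days),

```
T_ij  = mu_ij + e_ij,                 e_ij ~ N(0, sigma_e^2)
mu_ij = alpha + x_ij' beta + R_i + S_i
R_i ~ N(0, sigma_R^2)                               (unstructured)
S_i | S_-i ~ N( mean_{j in delta_i} S_j , sigma_S^2 / nu_i )   (ICAR)
```

where delta_i / nu_i are the set / number of wards contiguous with ward
i. Covariates are age (years), sex, and a seven-category ethnicity coded
as six dummies against a white British baseline. Six nested model forms
— every combination of {covariates} x {R} x {S} used in practice — are
fitted by a hand-written conjugate Gibbs sampler and compared by the
Deviance Information Criterion (DIC = Dbar + pD, lower is better). The
area-level variance share per MCMC iteration is
`100 * (sigma_R^2 + var(S)) / (sigma_R^2 + var(S) + sigma_e^2)`.

Because no patient-level data are distributable, `carlm.simulate`
generates complete synthetic datasets from the full generative process
(32-ward lattice, ~314 cases, residual log-scale SD 1.9, median DUP
~69.5 days, small ward-level components) — see `docs/methods.md`.

## Worked example

```python
import carlm

graph = carlm.make_lattice_graph(4, 8)                       # 32 wards
records, truth = carlm.simulate_dataset(graph, carlm.SimulationParams(seed=42))

m = carlm.HierarchicalModel.from_records(records, graph,
                                         carlm.model_spec("model2"))
res = m.fit(n_iter=6000, burn_in=2000, n_chains=2, seed=7)
print(res.summary().round(3))
print(f"DIC {res.dic:.2f}  pD {res.p_d:.2f}")
vp = res.variance_partition()
print(f"area share: {vp.median:.2f}% ({vp.lower:.3f}, {vp.upper:.2f})")
```

prints (309 simulated cases):

```
                      median   q2.5  q97.5
alpha                  1.843  1.134  2.545
beta_age               0.057  0.042  0.072
beta_sex_male          0.232 -0.186  0.667
beta_other_white      -0.128 -0.920  0.676
beta_black_caribbean   0.470 -0.102  1.043
beta_black_african     0.024 -0.702  0.749
beta_asian            -1.809 -2.735 -0.835
beta_mixed            -0.593 -1.359  0.183
beta_other             0.371 -0.582  1.329
sigma_e                1.894  1.751  2.061
sigma_R                0.097  0.004  0.454
DIC 1283.82  pD 12.42
area share: 0.26% (0.000, 5.59)
```

Read: each extra year of age raises expected log-DUP by ~0.057
(posterior median; the interval excludes 0), sigma_e recovers the
generating residual SD of 1.9, and the ward level holds well under 1% of
total variance at the posterior median — this dataset was generated with
only small ward effects, and the model says so.

The whole six-model ladder, with a comparison table, per-model reports
and a deterministic run manifest:

```python
config = carlm.RunConfig(
    seed=11, output_dir="out",
    synthetic=carlm.SyntheticBlock(4, 8, carlm.SimulationParams()),
    sampler=carlm.SamplerSettings(n_iter=6000, burn_in=2000, n_chains=2))
result = carlm.run_six_models(config)
print(result.comparison)     # six rows, DIC/pD per model, best flagged
```

The same analyses are scriptable from a shell via the `carlm` CLI
(`simulate`, `fit`, `ladder`, `subgroups`, `report`); real data enter as
a CSV of records plus a ward adjacency file (tab-separated edge list or
a GeoBUGS-style neighbour-list dialect).

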