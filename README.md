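# urbanvar

Multilevel phylogenetic meta-analysis of differences in the **mean** and the
**variation** of avian life-history traits between paired urban and non-urban
populations.

Urban ecology has documented many shifts in mean phenotypes (earlier laying,
smaller clutches), but whether city life also changes *phenotypic variation* —
the raw material of selection and plasticity — requires comparing second
moments across hundreds of published urban/non-urban comparisons. `urbanvar`
implements that comparative-variance meta-analysis as a tested, reusable
pipeline for three traits: laying date (days since 1 January), clutch size and
number of fledglings.

## What it computes

From per-arm summaries (mean $\bar{x}$, SD $s$, sample size $n$ per habitat)
it builds the standard effect sizes, with the urban arm in the numerator:

- **lnRR** $= \ln(\bar{x}_u/\bar{x}_c)$ — difference in means;
- **lnCVR** $= \ln(\mathrm{CV}_u/\mathrm{CV}_c) + \tfrac{1}{2(n_u-1)} -
  \tfrac{1}{2(n_c-1)}$ — difference in relative variability, which accounts
  for the mean–variance relationship;
- **lnVR**, **SMDH** and per-arm $(\ln s, \ln\bar{x})$ rows for sensitivity
  analyses.

Effect sizes $y_i$ with sampling variances $v_i$ are then modelled as

$$y_i \sim \mathcal{N}\!\big(X\beta,\; V(\theta)\big),\qquad
V(\theta) = Z_\tau T Z_\tau' + \sigma_v^2 Z_v Z_v' + \sigma_a^2 Z_a A Z_a'
          + \sigma_h^2 Z_h Z_h' + D_\varepsilon + \mathrm{diag}(v_i),$$

with study-by-trait deviations $\tau$ whose $3\times 3$ among-trait covariance
$T$ takes one of five structures (single variance, compound symmetric,
heteroscedastic CS, diagonal, unstructured; compared by ML/AIC),
population-pair intercepts, phylogenetic species effects correlated through
the shared-ancestry matrix $A$ (Grafen branch lengths), non-phylogenetic
species intercepts, and per-trait observation-level variances. Estimation is
from-scratch ML/REML (L-BFGS on log-variance/correlation transforms with
semi-analytic gradients), cross-checked against independent brute-force
likelihood evaluation and against `metafor::rma.mv` fits frozen into the test
suite. Heterogeneity is decomposed into multilevel $I^2$ components;
publication bias is probed with effective-sample-size and publication-year
meta-regressions ($R^2_{marginal}$); within/among-breeding-season variation is
separated by exact variance pooling; and landscape moderators (urban index
and the effective number of land covers, $\exp$ of the Shannon–Wiener index)
are extracted from categorical land-cover grids in buffers of 250–5000 m.

A synthetic-data generator mirrors all of this in the generative direction
with known truth, so estimator bias, RMSE and CI coverage are measurable.

## Worked example

```python
from urbanvar import synthetic_data as sd, effect_sizes as es, phylo, meta_engine as me

params = sd.SimulationParams(seed=7)          # defaults emulate the avian literature
records, truth = sd.simulate_dataset(params)  # ~400 paired comparisons, 35 species
A = phylo.correlation_from_newick(truth.tree_newick)

effects = es.compute_effects(records, "lnCVR")
spec = me.MetaModelSpec(fixed="trait", vcv_structure="diagonal",
                        obs_by_trait=True, method="REML")
fit = me.fit_meta(effects, spec, A)
print({k: round(v, 3) for k, v in fit.coef.items()})
print(round(es.percent_difference(fit.coef["mu:laying_date"]), 1), "% difference in CV")
```

Output:

```
{'mu:clutch_size': 0.061, 'mu:laying_date': 0.142, 'mu:n_fledglings': 0.022}
15.3 % difference in CV
```

The laying-date coefficient is the trait-level mean lnCVR: here a positive
value, i.e. urban populations show ~15% higher variation in laying date in
this simulated replicate (the generating truth is 0.176, within one standard
error). `fit.variance_components` holds the per-level variance estimates and
`me.i2_decomposition(fit)` expresses them as $I^2$ shares.

The same pipeline runs from the shell:

```bash
urbanvar simulate --seed 7 --out comparisons.csv --tree-out tree.nwk
urbanvar fit comparisons.csv --tree tree.nwk --models 1,3,4 --outdir results
urbanvar compare-vcv comparisons.csv --tree tree.nwk
```

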