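# robustblup

Robust alternatives to genomic best linear unbiased prediction (GBLUP)
for breeders and quantitative geneticists: maximum-a-posteriori
prediction of genetic values under Student-t (**TMAP**) and Laplace
(**LMAP**) residual distributions, computed by iteratively reweighted
mixed-model equations — no MCMC.

Gaussian mixed models shrink every record equally, which makes GBLUP
sensitive to outliers: records distorted by undeclared preferential
treatment, hidden structure, or unmodeled major genes.  Thick-tailed
residual distributions attenuate such records automatically.  For the
model

    y = Wα + Zg + e,   g ~ N(0, K σ_g²),   Var(e_i) = σ_e²/n_i,

with K a pedigree (A) or genomic (G) relationship matrix, all three
predictors solve Henderson-type equations; TMAP and LMAP re-iterate them
with per-record weights

    TMAP:  d_i = n_i / (1 + n_i (y_i−μ_i)² / (τ_e² ν)),   penalty λ″ = λ(ν−2)/(ν+1)
    LMAP:  m_i = n_i / |y_i−μ_i|,                          penalty ω = σ_e² / (2√2 σ_g²)

so poorly fitting records lose influence and their genetic values are
shrunk harder.  Around the predictors the package provides MINQUE
variance-component estimation over heritability grids, spectral maximum
likelihood, generalized cross-validation, exact and approximate
leave-one-out shortcuts, brute-force LOO with per-fold re-estimation,
paired bootstrap evaluation (PMSE, PCOR, predictive intercept/slope,
MNDCG), replicated train/test protocols, relationship-matrix
construction (VanRaden G, tabular A), and a synthetic-data generator
that reproduces the assumed model structure, including outlier
contamination.

See `docs/methods.md` for the full model description, numerical choices
and limitations.

## Worked example

Simulate 200 individuals (400 SNPs, heritability 0.3) with 10% of the
records shifted by 5 residual standard deviations — the "preferential
treatment" scenario — then compare methods by leave-one-out
cross-validation:

```sh
robustblup simulate --n 200 --markers 400 --seed 7 \
    --contamination 0.1 --shift 5 --out data
robustblup loo --phenotypes data/phenotypes.tsv --kinship data/kinship.tsv \
    --center --method gblup,tmap4,lmap --mode shortcut \
    --sigma-g2 0.3 --sigma-e2 0.7 --out loo.tsv
```

`loo.tsv` then contains:

```
method  metric  value
gblup   pmse    2.501447251
gblup   pcor    0.1050385746
gblup   alpha   0.0006632121288
gblup   beta    0.5440115215
tmap4   pmse    2.44427035
tmap4   pcor    0.1616690504
tmap4   alpha   -0.002293327672
tmap4   beta    1.05519652
lmap    pmse    2.197202347
lmap    pcor    0.3573203417
lmap    alpha   -0.003837866379
lmap    beta    1.186838713
```

Under contamination the robust methods predict held-out phenotypes
better than GBLUP: LMAP cuts the predictive mean-squared error from 2.50
to 2.20 and more than triples the predictive correlation, with TMAP-4 in
between; a predictive slope (beta) near 1 and intercept (alpha) near 0
indicate empirically unbiased predictions, and GBLUP's slope of 0.54
shows how the outliers distort its calibration.  The same comparison on
clean Gaussian data leaves GBLUP best, as theory says it should be.

The library mirrors the CLI one-to-one:

```python
from robustblup import (SimulationConfig, simulate_dataset, ModelData,
                        DispersionParams, fit_tmap, loo_shortcut)

sim = simulate_dataset(SimulationConfig(n_individuals=200, seed=7,
                                        contamination_fraction=0.1,
                                        contamination_shift=5.0))
data = ModelData(y=sim.y - sim.y.mean(), K=sim.K)
params = DispersionParams(sigma_g2=0.3, sigma_e2=0.7, nu=4.0)
fit = fit_tmap(data, params)          # weights in fit.weights
print(loo_shortcut(fit, data, params).metrics.pmse)
```

Other subcommands: `kinship` (G from dosages or A from a pedigree),
`fit` (full-data predictions, weights and convergence logs), `gcv`
(λ-grid generalized cross-validation), `cv` (replicated train/test over
heritability × ν grids with winner frequencies).  Every run writes a
YAML manifest from which it can be regenerated.

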