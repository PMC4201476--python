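# tilor — threshold index logistic regression for SNP case-control data

`tilor` models disease risk from categorical SNP genotypes (0/1/2 copies
of the variant allele) with an **additive threshold index logistic
regression**:

    P(Y = 1 | x) = logistic( g1(α'x) + g2(β'x) ),

    g_k(u) = b_k1 + b_k2·u   if u ≤ c_k,
             b_k3 + b_k4·u   if u >  c_k.

The unit-norm index vectors α, β combine many small per-SNP effects into
two scalar risk indices, and each two-regime link g_k lets the effect of
its index change qualitatively at an estimated threshold c_k — the
parametric expression of the idea that polygenic risk accumulates
quietly until a critical burden is crossed.  The model nests the linear
logit yet captures the nonlinear, interactive behaviour that linear
logistic regression misses on categorical genotype panels.

The package is aimed at statistical geneticists and biostatisticians
analysing moderate-size case-control panels (tens of SNPs after
screening, hundreds of subjects).  It provides:

- penalized maximum likelihood via a smoothing-homotopy gradient stage
  feeding multi-start downhill-simplex (Nelder-Mead) refinement, with
  exact renormalization to the identifiable canonical form;
- parametric-bootstrap standard errors for every parameter;
- univariate allelic odds-ratio screening of a large SNP panel;
- case/control-stratified k-fold cross-validation against a
  linear-logistic baseline (Type I/II error, accuracy, ROC/AUC);
- a synthetic-data generator and Monte Carlo parameter-recovery harness;
- a `tilor` command line (`screen | fit | bootstrap | cv | simulate`)
  reading delimited genotype tables (including the PLINK `.raw` dialect)
  and writing plain-TSV reports that embed the seed and configuration.

## Worked example

Fit the model to a synthetic 496-subject panel generated from the
packaged truth (8 SNPs, prevalence ≈ 0.6):

```python
import pandas as pd
import tilor
from tilor import ThresholdIndexLogit, FitConfig

truth = tilor.default_truth(8)
data = tilor.generate_dataset(truth, 496, seed=11)
df = pd.DataFrame(data.genotypes, columns=data.snp_ids)
df["phenotype"] = data.phenotype

model = ThresholdIndexLogit.from_dataframe(df)
res = model.fit(config=FitConfig(n_restarts=9, max_iterations=3000,
                                 simplex_tolerance=1e-8, polish_rounds=5,
                                 seed=0))
print(res.summary())
```

```
Threshold Index Logistic Regression Results
============================================================
No. observations: 496 (284 cases, 212 controls)   No. SNPs: 8
Log-likelihood: -238.6010   Penalized objective: -238.6013
Restarts: 9 (best: 5)   Converged: True   Seed: 0
P(alpha'x <= c1) = 64.31%   P(beta'x <= c2) = 77.82%
------------------------------------------------------------
link      b1      b2      b3     b4      c
  g1 -1.6442  0.8733  0.9782 0.7199 0.3749
  g2  0.4640 -1.6359 -2.0429 3.7432 0.1476
------------------------------------------------------------
snp_id   alpha    beta
  SNP1  0.6170  0.2705
  SNP2  0.3155  0.0762
  SNP3 -0.7059 -0.4588
  SNP4  0.0317 -0.1759
  SNP5  0.0277 -0.5716
  SNP6 -0.0063  0.5603
  SNP7 -0.1366 -0.1765
  SNP8 -0.0305  0.0882
```

Reading the output: the α index loads mainly on SNPs 1-3 and the β
index on SNPs 4-6 — matching the generating truth's supports (an index
is only identified up to sign and up to swapping the two index/link
pairs; here β came out sign-flipped, with its link mirrored
accordingly).  The below-threshold percentages say how many subjects sit
in each link's lower regime; g1's fitted regimes switch at c₁ ≈ 0.37
with clearly different slopes on either side.  `res.bootstrap_sd()`
adds parametric-bootstrap standard errors to the summary;
`res.plot_links()` draws the two fitted threshold links;
`tilor.run_cv_comparison(data, k=3, seed=1)` produces the fold-by-fold
Type I/II/accuracy/AUC table against the linear-logistic baseline.

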