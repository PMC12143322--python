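# latentfm

Latent-factor GWAS summary statistics and joint fine-mapping of any number
of uncorrelated latent factors.

## The problem

High-dimensional trait panels — complete blood counts, NMR metabolomics —
are usually analyzed one trait at a time, ignoring the shared biology that
makes the traits correlated.  `latentfm` is for statistical geneticists who
want to (1) summarize P correlated quantitative traits by K uncorrelated
latent factors via maximum-likelihood factor analysis with varimax rotation,
(2) obtain GWAS summary statistics for those factors — **without
individual-level data** — from the observed-trait summary statistics, the
trait covariance matrix, and the loading matrix, and (3) fine-map
association signals jointly across factors, gaining resolution when factors
share causal variants.

## The model

Traits follow the factor model `Y = M + L F + eps` with orthogonal factor
scores F (varimax keeps them uncorrelated).  Because the least-squares
scores `F = (L'L)^-1 L'(Y - Ybar)` are a fixed linear map of the traits,
per-variant factor GWAS coefficients satisfy the exact identity

    beta* = (L'L)^-1 L' beta,
    Var(beta*) = (L'L)^-1 L' V L (L'L)^-1,   V_ij = Cov(Y_i, Y_j) se_i se_j,

where beta stacks the per-trait marginal GWAS coefficients at a variant.
Fine-mapping scores multi-SNP causal configurations with conjugate
z-score/LD Bayes factors (Wakefield's form for single SNPs), a dynamic
maximum model size, and reports model posterior probabilities, per-variant
marginal posterior probabilities (MPP), and 99% credible sets (CS99).
Joint fine-mapping of M uncorrelated factors upweights model combinations
sharing at least one causal variant by `kappa^{1{overlap}} tau(s1, s2)`,
where `tau = 1/(1 - q + kappa q)` (q the size-dependent chance overlap
probability) keeps the prior over model sizes invariant to kappa.

## Worked example

One causal variant (`rs20`, standardized effect 0.10) shared by three latent
factors underlying six traits, n = 5,000 individuals, 40 variants in LD
(AR(1) rho = 0.6):

```python
import numpy as np, pandas as pd
from latentfm import *
from latentfm.finemap import RegionData
from latentfm.flashfm import flashfm_zero_with_finemap

G = simulate_genotypes(n=5000, p=40, mafs=np.full(40, 0.3), rho=0.6, seed=7)
L = pd.DataFrame(np.zeros((6, 3)), index=[f"T{i+1}" for i in range(6)],
                 columns=["F1", "F2", "F3"])
for i in range(6):
    L.iloc[i, i % 3] = 0.8
causal = {f: {"rs20": 0.10} for f in ["F1", "F2", "F3"]}
Y, truth = simulate_factor_traits(G, L, causal, factor_noise_sd=1.0,
                                  trait_noise_sd=0.5, seed=8)
Y = (Y - Y.mean()) / Y.std()

model = FactorModel.from_traits(Y)
print("parallel analysis selects K =", model.select_n_factors(seed=0))
res = model.fit(n_factors=3)

tables = [gwas_ols(G, Y[c].to_numpy(), trait=c) for c in Y.columns]
panel = harmonise(tables, min_maf=0.005, min_info=0.4)
latent = latent_sumstats_from_traits(panel, res.loading_matrix, Y.cov())
for ss in latent.factors:
    best = ss.table.loc[ss.table["P"].idxmin()]
    print(f"{ss.trait}: top variant {best['SNPID']} p = {best['P']:.2e}")

ld = np.corrcoef(G.dosages, rowvar=False)
regions = [RegionData(ss, ld, n=5000) for ss in latent.factors]
joint = flashfm_zero_with_finemap(regions, kappa=4.0)
print(joint.summary())
```

prints

```
parallel analysis selects K = 3
ML1: top variant rs20 p = 2.75e-04
ML2: top variant rs20 p = 3.12e-06
ML3: top variant rs20 p = 2.65e-06

flashfmZero joint fine-mapping of 3 factors (kappa=4.0, CS level 0.99)

factor  cmax_used single_top_variant  single_top_mpp  single_cs_size joint_top_variant  joint_top_mpp  joint_cs_size
   ML1          4               rs20          0.5807               6              rs20         0.9437              2
   ML2          4               rs20          0.9778               2              rs20         0.9974              1
   ML3          4               rs20          0.9661               2              rs20         0.9962              1
```

Reading the output: parallel analysis recovers the planted three factors;
every factor's strongest latent-GWAS association is the true causal variant
(note none of the six *individual traits* carries the full signal — the
factors concentrate it); single-factor fine-mapping leaves CS99s of 6, 2,
and 2 variants, and joint fine-mapping shrinks all three credible sets
(to 2, 1, 1) while raising the MPP of the true causal variant in each — the
resolution gain from sharing information across factors that have the same
causal variant.

A command-line interface mirrors the library
(`latentfm simulate | factors | latent-gwas | finemap | flashfmzero |
report | run`); `latentfm run --config config.yaml` executes the full
pipeline (harmonise, factor fit, latent GWAS, fine-mapping, joint
adjustment) and writes TSV summaries plus a JSON log of every filter count.

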