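# emeth

Reference-based cell-type deconvolution of DNA methylation data with an
EM algorithm that detects aberrant CpGs and down-weights them, plus
support for one cell type with known proportions but unknown reference
profile (the tumor-purity setting).

## The problem

Bulk tissue samples mix many cell types. Given Illumina 450k-style
beta-values `z_ki` (CpG `k`, sample `i`) and a reference matrix of cell
type-specific mean beta-values `nu_qk`, reference-based deconvolution
estimates the cell-type proportions `rho_qi` by regressing each bulk
profile on the reference columns. Two practical obstacles motivate this
package:

1. For some CpGs the reference does not describe the bulk sample
   (batch effects, cell-state differences): these **aberrant CpGs**
   corrupt naive regression estimates.
2. In tumor samples the tumor-cell methylation profile is unknown, but
   the tumor proportion `eta_i` (purity) is often known from copy-number
   data.

## The model

EMeth models each bulk beta-value by a two-component normal scale
mixture around the deconvolution mean:

    z_ki ~ pi_ai N(mu_ki, sigma_a^2 w_ki) + (1 - pi_ai) N(mu_ki, sigma_c^2 w_ki)
    mu_ki = eta_i nu_0k + sum_q rho_qi nu_qk,
    sum_q rho_qi = 1 - eta_i,  rho_qi >= 0,  sigma_a >= sigma_c

The aberrant component has inflated variance `sigma_a^2`; its posterior
probability `gamma_ki` automatically down-weights aberrant CpGs in the
proportion estimates. A ridge penalty `lambda * sum_q rho_qi^2`
stabilises the fit when reference profiles are collinear (CD4T vs CD8T
correlation can reach 0.96); the penalty weight is chosen by 5-fold
cross-validation over CpGs. The unknown profile `nu_0k` of the
no-reference cell type is estimable from variation of `eta` across
samples — per CpG it is the no-intercept regression slope of the
partial residual on `eta` — and is updated as a conditional-maximization
step inside the EM loop. Optional variants: binomial mean-variance
weights `w_ki`, and a Laplace (robust L1) error family.

The package also implements the four standard competitors (least
squares, Huber robust regression, linear-kernel support vector
regression, and non-negative least squares by quadratic programming),
a simulator reproducing the benchmark study design, and an RMSE
benchmark grid.

## Worked example

Simulate a benchmark-scale dataset (946 CpGs, 7 immune cell types with
the CD4T/CD8T pair correlated at 0.96, 100 bulk samples with tumor-style
purity `eta ~ U(0.3, 0.7)`, noise `sigma_c^2 = 0.00221`, aberrant/
consistent variance ratio 10) and fit EMeth:

```python
import numpy as np
import emeth

pool, reps = emeth.make_synthetic_reference(K_pool=2000, Q=7,
                                            collinear_pair_rho=0.96, seed=0)
keep = emeth.select_cpgs(reps, 946)
ref = emeth.ReferenceMatrix(tuple(pool.cpg_ids[k] for k in keep),
                            pool.cell_types, pool.values[keep])
bulk, truth = emeth.simulate_mixtures(
    ref, emeth.SimulationConfig(sigma_c2=0.00221, lambda_ratio=10, seed=1))
info = emeth.SampleInfo(truth.sample_ids, truth.true_eta)
fit = emeth.fit_emeth(bulk, ref, info, emeth.FitOptions(seed=1))

print("chosen ridge:", fit.chosen_ridge)
print("RMSE vs truth: %.4f"
      % emeth.compute_rmse(fit.proportions, truth.true_proportions))
print("corr(nu0_hat, nu0): %.3f"
      % np.corrcoef(fit.nu0, truth.true_nu0)[0, 1])
```

prints

```
chosen ridge: 94.60000000000001
RMSE vs truth: 0.0033
corr(nu0_hat, nu0): 1.000
```

The chosen ridge is `0.1 * K` — cross-validation picks the strongest
candidate penalty because of the collinear CD4T/CD8T pair. The overall
RMSE of the proportion estimates is 0.0033 (the four baselines land
near 0.03 on the same data), and the estimated methylation profile of
the no-reference cell type tracks the simulated truth almost perfectly.
The first estimated sample, `fit.proportions[:, 0] = (0.090, 0.030,
0.013, 0.174, 0.116, 0.027, 0.045)`, matches its ground truth
`(0.094, 0.030, 0.008, 0.171, 0.116, 0.031, 0.046)` with the remaining
mass `eta = 0.505` assigned to the no-reference type.

A command-line interface wraps the same steps:

```sh
emeth simulate --preset benchmark --sigma-c2 0.00221 --lambda-ratio 10 \
      --seed 1 --out data/
emeth deconvolve --bulk data/bulk.tsv --reference data/reference.tsv \
      --eta data/eta.tsv --method emeth --seed 1 --out fit/
emeth benchmark --repetitions 10 --seed 7 --out bench/
```

## Layout

| module | contents |
| --- | --- |
| `emeth.io` | domain types, invariants, TSV readers/writers |
| `emeth.core` | the EM estimator: E-step, QP M-step, ridge CV |
| `emeth.nu0` | no-reference cell-type profile estimation |
| `emeth.baselines` | LS / RLS / SVR / QP competitors |
| `emeth.simulate` | synthetic reference, mixture simulator, in-silico mixing |
| `emeth.benchmark` | RMSE metrics and the benchmark grid |
| `emeth.cli` | `emeth` command-line front end |

See `docs/methods.md` for the estimation details, numerical choices and
known limitations.
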