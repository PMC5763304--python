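# hksvm

SVM kernels for outcome prediction on high-dimensional expression data,
built around the **Hadamard kernel**

$$K_\alpha(\mathbf{x}_i,\mathbf{x}_j)=\sum_{k=1}^{p}\frac{|x_{ik}|^{\alpha}\,|x_{jk}|^{\alpha}}{2\left(|x_{ik}|^{\alpha}+|x_{jk}|^{\alpha}\right)},\qquad \alpha\neq 0,$$

where a coordinate with $x_{ik}=0$ or $x_{jk}=0$ contributes 0. Each
coordinate contributes half the harmonic mean of the two powered
magnitudes, so the kernel rewards features on which both samples are
strongly and similarly expressed — a natural similarity for non-negative,
right-skewed microarray/RNA-seq intensity matrices with far more features
than samples. Unlike its unpowered precursor
$K_0=\sum_k x_{ik}x_{jk}/(2(x_{ik}+x_{jk}))$, which is positive
semi-definite only for non-negative data, $K_\alpha$ is PSD for **every**
real data matrix, so it always defines a valid reproducing-kernel Hilbert
space for the SVM dual.

The package is aimed at computational biologists benchmarking classifiers
on small expression cohorts (tens to hundreds of samples, thousands of
features). It provides:

- **kernels** — Hadamard family $K_\alpha$, the precursor $K_0$, an
  unnormalized harmonic variant reproducing the classic signed
  counterexample, and the comparison kernels: linear
  $\mathbf{x}^T\mathbf{x}'$, quadratic $(\mathbf{x}^T\mathbf{x}'+1)^2$,
  Gaussian RBF $\exp(-\|\mathbf{x}-\mathbf{x}'\|^2/\sigma^2)$, and the
  denoised correlation kernel $1-e^{-\mathrm{corr}(\mathbf{x}_i,\mathbf{x}_j)}$
  with negative eigenvalues clipped to zero;
- **PSD certification** — Hadamard (entrywise) inverse, Cauchy-type
  reciprocal-sum matrices $V(i,j)=\sum_r 1/(X_{ir}+X_{jr})$, minimum
  eigenvalue / PSD checks, and eigenvalue-clip denoising;
- **normalization** — per-array mean scaling and quantile normalization;
- **evaluation** — soft-margin SVMs on precomputed Gram matrices
  (scikit-learn dual solver), ROC/AUC computed from first principles
  (trapezoid = Mann–Whitney with ties credited ½), repeated stratified
  k-fold CV with pooled out-of-fold scoring, and paired α/σ parameter
  sweeps;
- **synthetic data** — a log-normal two-class expression generator and
  survival-to-label derivation at a fixed prognosis horizon, so the whole
  pipeline is testable without downloading public accessions.

## Worked example

Compare all five kernels on a synthetic two-class cohort (40 samples ×
100 features; 10 features shifted 3-fold in the positive class) with 10
runs of stratified 5-fold cross-validation:

```python
import hksvm as hk

X, y = hk.generate_synthetic(hk.SyntheticConfig(seed=7))
cfg = hk.CVConfig(k=5, runs=10, seed=1)
for name, spec in [
    ("hadamard (alpha=1)", hk.KernelSpec("hadamard", alpha=1.0)),
    ("linear", hk.KernelSpec("linear")),
    ("quadratic", hk.KernelSpec("polynomial", degree=2)),
    ("rbf (sigma=100)", hk.KernelSpec("rbf", sigma=100.0)),
    ("correlation (denoised)", hk.KernelSpec("correlation_denoised")),
]:
    res = hk.cross_validate(X, y, spec, cfg=cfg)
    print(f"{name:24s} AUC {res.summary()}")
```

prints

```
hadamard (alpha=1)       AUC 0.9992 ± 0.0017
linear                   AUC 0.9762 ± 0.0117
quadratic                AUC 0.9755 ± 0.0114
rbf (sigma=100)          AUC 0.9488 ± 0.0144
correlation (denoised)   AUC 0.9758 ± 0.0118
```

Each line is the mean ± sample sd of ten per-run AUCs; each run's AUC
pools the out-of-fold decision scores of one 5-fold split, so 0.5 is
chance ranking of the two outcome groups and 1.0 is perfect separation.
On this cohort the Hadamard kernel separates the classes almost
perfectly and more stably than the comparison kernels.

The `examples/` directory holds one short script per capability: the PSD
counterexample and its repair (`01`), the kernel comparison above (`02`),
the α sweep (`03`), normalization effects under per-array scale drift
(`04`), and survival-based labeling (`05`).

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
hksvm simulate --n-per-class 20 --p 100 --seed 7 --out-dir cohort/
hksvm gram cohort/expression.tsv --kernel hadamard --alpha 1.0 --out gram.tsv
hksvm psd-check gram.tsv
hksvm eval cohort/expression.tsv --labels cohort/labels.tsv --runs 10 --seed 1 --out-dir results/
hksvm sweep cohort/expression.tsv --labels cohort/labels.tsv --param alpha --out-dir sweep/
```

Every command is deterministic given `--seed`, logs to stderr, and writes
its serialized run configuration next to its outputs.

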