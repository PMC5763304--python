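# Methods

## The Hadamard kernel and its PSD theory

For samples $\mathbf{x}_i \in \mathbb{R}^p$ the Hadamard kernel is

$$K_\alpha(\mathbf{x}_i,\mathbf{x}_j)=\sum_{k=1}^{p}\frac{|x_{ik}|^{\alpha}|x_{jk}|^{\alpha}}{2(|x_{ik}|^{\alpha}+|x_{jk}|^{\alpha})},\qquad \alpha\neq 0 .$$

Each coordinate contributes half the harmonic mean of the powered
magnitudes $|x_{ik}|^\alpha$ and $|x_{jk}|^\alpha$. The zero convention —
a coordinate contributes 0 whenever **either** value is exactly 0 — is
applied before exponentiation, which keeps the kernel symmetric (the
one-sided statement of the rule would not be) and keeps $\alpha<0$
well-defined: zeros never reach the power. Any real $\alpha \neq 0$ is
accepted; the conventional sweep uses $\alpha \in (0,5)$.

Positive semi-definiteness is certified constructively, and the
construction's primitives are public API so the argument itself is
testable:

1. `hadamard_inverse` — the entrywise reciprocal $A^{\circ(-1)}$ of a
   no-zero-entry matrix; an involution.
2. `reciprocal_sum_gram` — the Cauchy-type matrix
   $V_X(i,j)=\sum_r 1/(X_{ir}+X_{jr})$. Over feature columns it
   decomposes as $V_X = \sum_r V_{w_r}$, with
   $V_w(i,j) = 1/(w_i+w_j)$ (`cauchy_gram`). For positive $w$ the matrix
   $(w_i + w_j)$ is rank-2 with exactly one positive eigenvalue, and the
   entrywise reciprocal of such a matrix is PSD (the Bapat/Reams
   property), so each $V_{w_r}$ — hence $V_X$ — is PSD.
3. On positive data $K_0(X) = \tfrac12 V_{X^{\circ(-1)}}$ entrywise, so
   $K_0$ is PSD there; zero coordinates only delete rows of the
   construction, extending the result to non-negative data; and
   $K_\alpha(X) = K_0(|X|^{\circ\alpha})$ with $|X|^{\circ\alpha}$
   non-negative, which proves PSD-ness of $K_\alpha$ for arbitrary real
   data.

Tests exercise every link of this chain numerically: the identity
$K_0 \equiv \tfrac12 V_{X^{\circ(-1)}}$ to 1e-12 relative, the
column-wise decomposition with each term individually PSD, and a
200-matrix random sweep (signed entries, planted zeros, n ≤ 30, p ≤ 50,
$\alpha \in \{0.2, 0.5, 1, 2, 4\}$) asserting
$\lambda_{\min} \geq -10^{-8}\max(1,\lambda_{\max})$.

### The signed counterexample

Without absolute values $K_0$ fails on signed data. Two conventions of
the counterexample kernel circulate — the $K_0$ formula itself and the
unnormalized harmonic sum $\sum_k 2x_{ik}x_{jk}/(x_{ik}+x_{jk})$, which
is exactly $4K_0$ — and the classic printed 2×2 counterexample
($x_1$ the 1-vector, $x_2$ the $-\tfrac12$-vector, entries
$n, -2n, -n/2$) follows the latter. Both are kept as distinct operations
(`k0_gram`, `harmonic_example_gram`) rather than silently reconciling the
factor of 4, so the formula and the printed matrix are each reproducible;
the indefiniteness witness is the pair of quadratic forms
$v^TKv = -7n/2$ for $v=[1,1]$ and $+n$ for $v=[-1,0]$. On signed data a
coordinate pair with $x_{ik}+x_{jk}=0$ but $x_{ik}x_{jk}\neq 0$ makes the
formula undefined; this raises an error naming the sample pair instead of
returning ±inf.

## Comparison kernels

Linear $\mathbf{x}^T\mathbf{x}'$; polynomial
$(\mathbf{x}^T\mathbf{x}'+1)^d$ with $d=2$ the quadratic kernel of the
comparison; Gaussian RBF $\exp(-\|\mathbf{x}-\mathbf{x}'\|^2/\sigma^2)$
— the alternative parameterization $\exp(-d\|\cdot\|^2)$ maps to
$d = 1/\sigma^2$, and $\sigma$ is the configured parameter with default
sweep grid $\{10^{-2},10^{-1},1,10,100,1000\}$. The correlation kernel is
built in three steps: $K_{CB}(i,j) = 1-e^{-\mathrm{corr}(\mathbf{x}_i,\mathbf{x}_j)}$
with Pearson correlation **between sample rows** (the Gram must be
$n\times n$), eigendecomposition, and clipping of negative eigenvalues at
exactly 0 before reconstruction ($K_{DCB}$). The input is symmetrized as
$(K+K^T)/2$ before decomposition to absorb round-off; the clip is
idempotent and leaves an already-PSD matrix unchanged to 1e-10. No
general nearest-PSD projection is attempted — clipping is the method.

Out-of-sample prediction needs kernel values between held-out and
training samples. All families except the correlation kernel are
evaluated pairwise. The correlation kernel has no natural out-of-sample
form because clipping couples all entries; `cross_gram` therefore
denoises the Gram of the row concatenation [train; test] and slices the
test × train block. This is transductive — it uses test *feature
vectors* — but never test labels. Inside cross-validation the union of a
fold's train and test sets is the full cohort, and eigenvalue clipping is
permutation-equivariant, so slicing the full-cohort denoised Gram is
exactly the concat-then-slice rule; one decomposition per repetition
suffices.

## Normalization

`mean_scale` divides each array (= sample row) by its own mean intensity,
leaving every sample with mean exactly 1; idempotent; a zero-mean sample
(possible on log-ratio data) is an error rather than a silent division.
`quantile_normalize` is the classic rank-mean transform: sort each
sample, average across samples at each rank, map the rank-means back
through each sample's ordering; ties within a sample receive the mean of
the rank-means they span (the standard deterministic convention). With
ties the output multisets can differ between samples — strict
distribution identity holds for tie-free (continuous) data, which is
what the contract tests use. By default normalization is fitted on the
full matrix before CV splitting, matching the usual array-processing
workflow; this is a known train/test leakage caveat, and
`per_fold_normalization=True` renormalizes train and test blocks
independently inside each fold instead.

## SVM and evaluation protocol

The classifier is the soft-margin SVM in dual form, consumed through a
precomputed-Gram contract: training takes an $n\times n$ Gram and ±1
labels and returns dual coefficients $a_i \in [0, C]$ with
$\sum_i a_i y_i = 0$ and bias $b$; the decision score for a test row of
kernel values $k$ is $\sum_i a_i y_i k_i + b$, positive favouring class
+1. The quadratic program is solved by scikit-learn's `SVC`
(`kernel="precomputed"`); the package asserts the dual constraints on the
returned model rather than re-implementing the solver. $C$ defaults to 1
and is configurable — small expression cohorts are rarely sensitive to it
in the separable regime, and the protocol does not tune it.

ROC and AUC are computed from first principles: the curve sweeps all
score thresholds with tied scores grouped into single steps, and the
trapezoidal area then equals the Mann–Whitney statistic
$(\#\{s_+>s_-\} + \tfrac12\#\{s_+=s_-\})/(n_+ n_-)$ — an identity the
tests check exactly against the exhaustive pairwise computation and
against scikit-learn's `roc_auc_score`. Confusion counts at a fixed
threshold (default 0) are available but AUC never depends on them.

The headline protocol is stratified 5-fold CV repeated 10 times. Folds
are dealt deterministically from a seeded generator, round-robin over
shuffled within-class indices with a counter running across classes, so
overall fold sizes and per-fold class counts each differ by at most one.
Stratification is the default because small cohorts are often imbalanced
enough for unstratified folds to go single-class; if a class has fewer
members than folds, splitting degrades to a plain shuffle with a warning.
Each repetition yields **one** AUC from the pooled out-of-fold scores
(stable when folds are small; `score_mode="per_fold_mean"` gives the
fold-averaged alternative), and results are reported as mean ± sd
(ddof=1) over repetitions. Parameter sweeps (α over 0.1–4.9 step 0.1 by
default; σ over the decade grid) reuse identical fold partitions across
grid values so comparisons are paired.

## Synthetic cohorts and labels

The generator emulates a two-class intensity matrix:
$x_{ij} = \exp(\mu_j + \varepsilon_{ij})$ with feature baselines
$\mu_j \sim N(5, 1)$ on the natural-log scale (median intensity ≈ 150,
microarray-like right skew, strictly positive) and noise
$\varepsilon_{ij} \sim N(0, \text{noise\_sd})$; the first
`n_informative` features are multiplied by `effect` in the +1 class.
Defaults — 20 samples per class, 100 features, 10 informative, 3-fold
effect, noise sd 0.5 — give a cohort of realistic shape (n ≪ p, minority
of informative features) that a good kernel should separate nearly
perfectly and that becomes an exact null at `effect=1`. What the
generator does **not** emulate: probe-level artefacts, batch effects,
heavy-tailed count noise, censoring structure, or correlated gene
modules; passing tests on it demonstrate correctness of the machinery and
sensible relative behaviour of the kernels, not clinical performance on
real cohorts.

Survival-to-label derivation at a horizon (default 5 years): an event
before the cutoff → −1; follow-up reaching the cutoff (event or not) →
+1, with time exactly at the cutoff counting as reached; censored before
the cutoff → excluded, because the status at the horizon is unknown and
imputation would bias the AUC. A polarity flip is exposed
(`positive_is_survivor=False`); AUC is invariant under a consistent flip
plus score negation.

## Numerical choices

- Symmetry is enforced exactly on every Gram by averaging with the
  transpose after entrywise construction; the `GramMatrix` container
  rejects asymmetry beyond 1e-10 relative.
- PSD checks use the relative rule
  $\lambda_{\min} \geq -\text{tol}\cdot\max(1, \lambda_{\max})$ with
  tol = 1e-8, on the symmetrized matrix via `eigvalsh`.
- Gram files are delimited text with a one-line header naming family and
  parameters, entries at 15 significant digits, so round-trips preserve
  values to full double precision.
- Per-run fold seeds derive from the base seed as
  $(\text{seed} + 1000003 \cdot \text{run}) \bmod (2^{31}-1)$, keeping
  every derived seed a valid 31-bit integer.
- Degenerate inputs fail loudly with positions: NaN cells on read,
  zero-variance samples in the correlation kernel, zero entries under the
  Hadamard inverse, cancelling signed pairs in $K_0$, zero-mean samples
  in mean scaling.

## Known limitations

- No approximate or low-rank kernel computation: Gram construction is
  $O(n^2 p)$ and eigendecomposition $O(n^3)$, fine for cohort-sized n.
- The transductive correlation-kernel extension means its CV estimates
  are not strictly inductive (test features inform the clipping), which
  mirrors how the kernel is defined rather than a correctable defect.
- No nested CV: sweep argmaxes are descriptive, and selecting α or σ by
  the same CV that reports performance is optimistically biased.
- No probe summarization, background correction, log-transform pipelines,
  GEO parsing or downloading; external matrices enter as delimited text.
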