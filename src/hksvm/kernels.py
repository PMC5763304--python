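"""Kernel constructions for expression-based SVM classification.

The centrepiece is the Hadamard kernel

    K_alpha(x, y) = sum_k |x_k|^a |y_k|^a / (2 (|x_k|^a + |y_k|^a)),

a sum of scaled harmonic means of powered coordinate magnitudes.  A
coordinate where either sample is exactly 0 contributes 0 (the zero
convention, applied before exponentiation so negative exponents never
produce infinities).  K_alpha is positive semi-definite for *every* real
data matrix; the unpowered precursor K_0 (no absolute values) is PSD only
on non-negative data, and an explicit indefinite counterexample on signed
data is provided as :func:`harmonic_example_gram`.

The PSD argument rests on two primitives kept as public operations: the
Hadamard (entrywise) inverse, and the Cauchy-type matrix V(i,j) =
sum_r 1/(X_ir + X_jr), which decomposes over feature columns into rank-one
reciprocal terms 1/(w_i + w_j), each PSD for positive w.

Comparison kernels: linear, polynomial (degree 2 = quadratic), Gaussian
RBF exp(-||x-y||^2 / sigma^2), and the correlation kernel
1 - exp(-corr(x_i, x_j)) made PSD by clipping negative eigenvalues to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .expression import ExpressionMatrix

__all__ = [
    "KernelSpec",
    "GramMatrix",
    "CrossGram",
    "EigenClip",
    "FAMILIES",
    "hadamard_entry",
    "hadamard_gram",
    "k0_gram",
    "harmonic_example_gram",
    "linear_gram",
    "polynomial_gram",
    "rbf_gram",
    "correlation_base_gram",
    "correlation_denoised_gram",
    "denoise_to_psd",
    "gram_matrix",
    "cross_gram",
    "hadamard_inverse",
    "reciprocal_sum_gram",
    "cauchy_gram",
    "min_eigenvalue",
    "is_psd",
    "write_gram",
    "read_gram",
]

FAMILIES = (
    "hadamard",
    "k0",
    "harmonic_unnormalized",
    "linear",
    "polynomial",
    "rbf",
    "correlation_denoised",
)

_SYM_RTOL = 1e-10
_PSD_TOL = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family together with its parameter.

    ``alpha`` (any real != 0) applies to ``hadamard``; ``sigma`` (> 0) to
    ``rbf``; ``degree`` (integer >= 1, default 2 = the quadratic kernel) to
    ``polynomial``.  Parameters irrelevant to the family are ignored.
    """

    family: str
    alpha: float | None = None
    sigma: float | None = None
    degree: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {FAMILIES}")
        if self.family == "hadamard":
            a = 1.0 if self.alpha is None else float(self.alpha)
            if a == 0 or not math.isfinite(a):
                raise ValueError("hadamard kernel requires finite alpha != 0")
            object.__setattr__(self, "alpha", a)
        else:
            object.__setattr__(self, "alpha", None)
        if self.family == "rbf":
            s = 1.0 if self.sigma is None else float(self.sigma)
            if not (s > 0 and math.isfinite(s)):
                raise ValueError("rbf kernel requires sigma > 0")
            object.__setattr__(self, "sigma", s)
        else:
            object.__setattr__(self, "sigma", None)
        if self.family == "polynomial":
            d = 2 if self.degree is None else int(self.degree)
            if d < 1:
                raise ValueError("polynomial degree must be >= 1")
            object.__setattr__(self, "degree", d)
        else:
            object.__setattr__(self, "degree", None)

    def describe(self) -> str:
        parts = [f"family={self.family}"]
        for name in ("alpha", "sigma", "degree"):
            v = getattr(self, name)
            if v is not None:
                parts.append(f"{name}={v:.15g}" if isinstance(v, float) else f"{name}={v}")
        return " ".join(parts)


@dataclass(frozen=True)
class GramMatrix:
    """Symmetric ``n x n`` kernel matrix over one sample set."""

    values: np.ndarray
    spec: KernelSpec
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError(f"Gram matrix must be square, got shape {K.shape}")
        scale = max(1.0, float(np.abs(K).max(initial=0.0)))
        if np.abs(K - K.T).max(initial=0.0) > _SYM_RTOL * scale:
            raise ValueError("Gram matrix is not symmetric within tolerance")
        ids = tuple(self.sample_ids) or tuple(f"S{i + 1}" for i in range(K.shape[0]))
        if len(ids) != K.shape[0]:
            raise ValueError("sample_ids length does not match Gram size")
        object.__setattr__(self, "values", K)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CrossGram:
    """``n_test x n_train`` kernel evaluations between two sample sets."""

    values: np.ndarray
    spec: KernelSpec

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2:
            raise ValueError("cross-Gram must be 2-D")
        object.__setattr__(self, "values", V)


@dataclass(frozen=True)
class EigenClip:
    """Record of one eigenvalue-clipping pass (spectra before/after)."""

    eigenvalues_before: np.ndarray
    eigenvalues_after: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self) -> None:
        V = np.asarray(self.eigenvectors, dtype=float)
        n = V.shape[0]
        if np.abs(V.T @ V - np.eye(n)).max() > 1e-8:
            raise ValueError("eigenvector matrix is not orthonormal within 1e-8")


# ---------------------------------------------------------------------------
# Hadamard family


def _as_matrix(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    A = np.asarray(X, dtype=float)
    if A.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite entries in input matrix")
    return A


def _ids(X: ExpressionMatrix | np.ndarray) -> tuple[str, ...]:
    return X.sample_ids if isinstance(X, ExpressionMatrix) else ()


def _powered_magnitudes(A: np.ndarray, alpha: float) -> np.ndarray:
    """|A|^alpha with the zero convention applied before exponentiation."""
    M = np.abs(A)
    out = np.zeros_like(M)
    nz = M > 0
    out[nz] = M[nz] ** alpha
    return out


def hadamard_entry(x: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Single Hadamard-kernel evaluation between two sample vectors.

    Symmetric in ``(x, y)`` and invariant to sign flips of any coordinate.
    """
    if alpha == 0:
        raise ValueError("alpha must be nonzero")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    a = _powered_magnitudes(x[None, :], alpha)[0]
    b = _powered_magnitudes(y[None, :], alpha)[0]
    num = a * b
    live = num > 0
    return float(np.sum(num[live] / (2.0 * (a[live] + b[live]))))


def _hadamard_block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Harmonic-mean block between powered-magnitude matrices (rows x rows)."""
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        num = A[i] * B  # (nB, p); both factors >= 0
        den = A[i] + B
        contrib = np.divide(num, 2.0 * den, out=np.zeros_like(num), where=num > 0)
        out[i] = contrib.sum(axis=1)
    return out


def hadamard_gram(X: ExpressionMatrix | np.ndarray, alpha: float = 1.0) -> GramMatrix:
    """Hadamard-kernel Gram matrix; PSD for every real data matrix."""
    if alpha == 0:
        raise ValueError("alpha must be nonzero")
    A = _powered_magnitudes(_as_matrix(X), alpha)
    K = _hadamard_block(A, A)
    K = (K + K.T) / 2.0  # exact symmetry despite float summation order
    return GramMatrix(K, KernelSpec("hadamard", alpha=alpha), _ids(X))


def _signed_harmonic_block(
    A: np.ndarray, B: np.ndarray, scale: float, ids_a: tuple[str, ...], ids_b: tuple[str, ...]
) -> np.ndarray:
    """sum_k A_ik B_jk / (scale * (A_ik + B_jk)) with the zero convention.

    Raises on a coordinate pair whose values cancel (x + y = 0, x*y != 0),
    which can only happen on signed data.
    """
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        num = A[i] * B
        den = A[i] + B
        live = num != 0
        if np.any(live & (den == 0)):
            j, _ = np.argwhere(live & (den == 0))[0]
            sa = ids_a[i] if ids_a else f"#{i + 1}"
            sb = ids_b[j] if ids_b else f"#{j + 1}"
            raise ZeroDivisionError(
                f"samples {sa} and {sb} have cancelling coordinates (x + y = 0, x*y != 0); "
                "kernel undefined on this signed pair"
            )
        out[i] = np.divide(num, scale * den, out=np.zeros_like(num), where=live).sum(axis=1)
    return out


def k0_gram(X: ExpressionMatrix | np.ndarray) -> GramMatrix:
    """Unpowered precursor kernel sum_k x_ik x_jk / (2 (x_ik + x_jk)).

    Equals ``hadamard_gram(X, 1)`` on non-negative data, where it is PSD;
    on signed data it may be indefinite and cancelling coordinate pairs
    raise ``ZeroDivisionError``.
    """
    A = _as_matrix(X)
    ids = _ids(X)
    K = _signed_harmonic_block(A, A, 2.0, ids, ids)
    K = (K + K.T) / 2.0
    return GramMatrix(K, KernelSpec("k0"), ids)


def harmonic_example_gram(X: ExpressionMatrix | np.ndarray) -> GramMatrix:
    """Unnormalized harmonic-sum kernel sum_k 2 x_ik x_jk / (x_ik + x_jk).

    This is exactly 4x :func:`k0_gram` wherever both are defined.  It is the
    convention that reproduces the classic signed counterexample: for
    x1 = ones(n), x2 = -ones(n)/2 the Gram is [[n, -2n], [-2n, -n/2]],
    which is indefinite.
    """
    A = _as_matrix(X)
    ids = _ids(X)
    K = _signed_harmonic_block(A, A, 0.5, ids, ids)
    K = (K + K.T) / 2.0
    return GramMatrix(K, KernelSpec("harmonic_unnormalized"), ids)


# ---------------------------------------------------------------------------
# Comparison kernels


def linear_gram(X: ExpressionMatrix | np.ndarray) -> GramMatrix:
    A = _as_matrix(X)
    K = A @ A.T
    return GramMatrix((K + K.T) / 2.0, KernelSpec("linear"), _ids(X))


def polynomial_gram(X: ExpressionMatrix | np.ndarray, degree: int = 2) -> GramMatrix:
    if int(degree) < 1:
        raise ValueError("degree must be >= 1")
    A = _as_matrix(X)
    K = (A @ A.T + 1.0) ** int(degree)
    return GramMatrix((K + K.T) / 2.0, KernelSpec("polynomial", degree=degree), _ids(X))


def rbf_gram(X: ExpressionMatrix | np.ndarray, sigma: float = 1.0) -> GramMatrix:
    """Gaussian kernel exp(-||x_i - x_j||^2 / sigma^2); unit diagonal."""
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    A = _as_matrix(X)
    K = np.exp(-cdist(A, A, "sqeuclidean") / sigma**2)
    return GramMatrix((K + K.T) / 2.0, KernelSpec("rbf", sigma=sigma), _ids(X))


def correlation_base_gram(X: ExpressionMatrix | np.ndarray) -> GramMatrix:
    """Preliminary correlation kernel 1 - exp(-corr(x_i, x_j)).

    ``corr`` is the Pearson correlation between sample rows, so the result
    is n x n.  May be indefinite; see :func:`denoise_to_psd`.
    """
    A = _as_matrix(X)
    ids = _ids(X)
    if A.shape[1] < 2:
        raise ValueError("sample correlation needs at least 2 features")
    sd = A.std(axis=1)
    if np.any(sd == 0):
        i = int(np.flatnonzero(sd == 0)[0])
        sid = ids[i] if ids else f"#{i + 1}"
        raise ValueError(f"sample {sid} has zero variance across features; correlation undefined")
    C = np.corrcoef(A)
    K = 1.0 - np.exp(-C)
    return GramMatrix((K + K.T) / 2.0, KernelSpec("correlation_denoised"), ids)


def denoise_to_psd(K: GramMatrix | np.ndarray) -> tuple[GramMatrix, EigenClip]:
    """Clip negative eigenvalues to zero and reconstruct.

    The matrix is symmetrized as (K + K^T)/2 before decomposition to absorb
    round-off; clipping threshold is exactly 0.  Idempotent, and the
    identity on matrices that are already PSD.
    """
    spec = K.spec if isinstance(K, GramMatrix) else KernelSpec("correlation_denoised")
    ids = K.sample_ids if isinstance(K, GramMatrix) else ()
    A = K.values if isinstance(K, GramMatrix) else np.asarray(K, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("denoising requires a square matrix")
    scale = max(1.0, float(np.abs(A).max(initial=0.0)))
    if np.abs(A - A.T).max(initial=0.0) > 1e-8 * scale:
        raise ValueError("matrix is asymmetric beyond tolerance; not a Gram candidate")
    S = (A + A.T) / 2.0
    w, V = np.linalg.eigh(S)
    w_clip = np.maximum(w, 0.0)
    D = (V * w_clip) @ V.T
    D = (D + D.T) / 2.0
    return GramMatrix(D, spec, ids), EigenClip(w, w_clip, V)


def correlation_denoised_gram(X: ExpressionMatrix | np.ndarray) -> GramMatrix:
    """Full three-step correlation kernel: base kernel then eigenvalue clip."""
    denoised, _ = denoise_to_psd(correlation_base_gram(X))
    return denoised


# ---------------------------------------------------------------------------
# Dispatch and out-of-sample evaluation


def gram_matrix(spec: KernelSpec, X: ExpressionMatrix | np.ndarray) -> GramMatrix:
    """Compute the Gram matrix for any kernel family."""
    if spec.family == "hadamard":
        return hadamard_gram(X, spec.alpha)
    if spec.family == "k0":
        return k0_gram(X)
    if spec.family == "harmonic_unnormalized":
        return harmonic_example_gram(X)
    if spec.family == "linear":
        return linear_gram(X)
    if spec.family == "polynomial":
        return polynomial_gram(X, spec.degree)
    if spec.family == "rbf":
        return rbf_gram(X, spec.sigma)
    if spec.family == "correlation_denoised":
        return correlation_denoised_gram(X)
    raise ValueError(f"unknown kernel family {spec.family!r}")


def cross_gram(
    spec: KernelSpec,
    X_train: ExpressionMatrix | np.ndarray,
    X_test: ExpressionMatrix | np.ndarray,
) -> CrossGram:
    """Kernel evaluations between held-out and training samples.

    Entry ``(i, j)`` is the kernel between test sample ``i`` and training
    sample ``j``.  The correlation kernel has no natural out-of-sample
    form, so it is computed transductively: denoise the Gram of the row
    concatenation [train; test] and slice the test x train block.  Test
    *labels* are never involved.
    """
    A = _as_matrix(X_train)
    B = _as_matrix(X_test)
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: train has {A.shape[1]}, test has {B.shape[1]}"
        )
    if spec.family == "hadamard":
        Pa = _powered_magnitudes(A, spec.alpha)
        Pb = _powered_magnitudes(B, spec.alpha)
        V = _hadamard_block(Pb, Pa)
    elif spec.family == "k0":
        V = _signed_harmonic_block(B, A, 2.0, _ids(X_test), _ids(X_train))
    elif spec.family == "harmonic_unnormalized":
        V = _signed_harmonic_block(B, A, 0.5, _ids(X_test), _ids(X_train))
    elif spec.family == "linear":
        V = B @ A.T
    elif spec.family == "polynomial":
        V = (B @ A.T + 1.0) ** spec.degree
    elif spec.family == "rbf":
        V = np.exp(-cdist(B, A, "sqeuclidean") / spec.sigma**2)
    elif spec.family == "correlation_denoised":
        stacked = np.vstack([A, B])
        denoised = correlation_denoised_gram(stacked)
        V = denoised.values[A.shape[0] :, : A.shape[0]]
    else:
        raise ValueError(f"unknown kernel family {spec.family!r}")
    return CrossGram(V, spec)


# ---------------------------------------------------------------------------
# PSD-theory primitives


def hadamard_inverse(A: np.ndarray) -> np.ndarray:
    """Entrywise reciprocal A -> (1 / a_ij); an involution.

    Every entry must be nonzero; the first offending position is reported
    1-based.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A == 0):
        i, j = np.argwhere(A == 0)[0]
        raise ZeroDivisionError(f"zero entry at position ({i + 1}, {j + 1})")
    return 1.0 / A


def reciprocal_sum_gram(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Cauchy-type matrix V(i, j) = sum_r 1 / (X_ir + X_jr).

    For positive X this is a sum over feature columns of PSD reciprocal
    matrices 1/(w_i + w_j) (:func:`cauchy_gram`), hence PSD; and
    ``k0_gram(X).values == reciprocal_sum_gram(hadamard_inverse(X)) / 2``.
    """
    A = _as_matrix(X)
    n = A.shape[0]
    V = np.empty((n, n))
    for i in range(n):
        den = A[i] + A  # (n, p)
        if np.any(den == 0):
            j, r = np.argwhere(den == 0)[0]
            raise ZeroDivisionError(
                f"zero denominator: X[{i + 1},{r + 1}] + X[{j + 1},{r + 1}] = 0"
            )
        V[i] = (1.0 / den).sum(axis=1)
    return (V + V.T) / 2.0


def cauchy_gram(w: np.ndarray) -> np.ndarray:
    """Reciprocal-sum matrix 1/(w_i + w_j); PSD for strictly positive w."""
    w = np.asarray(w, dtype=float).ravel()
    den = w[:, None] + w[None, :]
    if np.any(den == 0):
        i, j = np.argwhere(den == 0)[0]
        raise ZeroDivisionError(f"w[{i + 1}] + w[{j + 1}] = 0")
    return 1.0 / den


def min_eigenvalue(K: GramMatrix | np.ndarray) -> float:
    """Smallest eigenvalue of the symmetrized matrix."""
    A = K.values if isinstance(K, GramMatrix) else np.asarray(K, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("eigenvalues require a square matrix")
    return float(np.linalg.eigvalsh((A + A.T) / 2.0)[0])


def is_psd(K: GramMatrix | np.ndarray, tol: float = _PSD_TOL) -> bool:
    """PSD within relative tolerance: min eig >= -tol * max(1, max eig)."""
    A = K.values if isinstance(K, GramMatrix) else np.asarray(K, dtype=float)
    w = np.linalg.eigvalsh((A + A.T) / 2.0)
    return bool(w[0] >= -tol * max(1.0, float(w[-1])))


# ---------------------------------------------------------------------------
# Gram I/O (delimited text, deterministic 15-significant-digit formatting)


def write_gram(gram: GramMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kernel {gram.spec.describe()} n={gram.n}\n")
        fh.write("sample\t" + "\t".join(gram.sample_ids) + "\n")
        for sid, row in zip(gram.sample_ids, gram.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.15g}" for v in row) + "\n")


def _parse_header(line: str) -> KernelSpec:
    tokens = line.lstrip("# ").split()
    fields: dict[str, str] = {}
    for tok in tokens[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            fields[k] = v
    family = fields.get("family")
    if family is None:
        raise ValueError("Gram file header missing 'family='")
    return KernelSpec(
        family,
        alpha=float(fields["alpha"]) if "alpha" in fields else None,
        sigma=float(fields["sigma"]) if "sigma" in fields else None,
        degree=int(fields["degree"]) if "degree" in fields else None,
    )


def read_gram(path: str | Path) -> GramMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# kernel ...' header line")
        spec = _parse_header(header)
        ids = tuple(fh.readline().rstrip("\n").split("\t")[1:])
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    return GramMatrix(np.asarray(rows), spec, ids)


def iter_specs(
    family: str,
    alphas: Iterable[float] = (),
    sigmas: Iterable[float] = (),
) -> list[KernelSpec]:
    """Helper to expand a parameter grid into KernelSpecs (used by sweeps)."""
    if family == "hadamard":
        return [KernelSpec("hadamard", alpha=a) for a in alphas]
    if family == "rbf":
        return [KernelSpec("rbf", sigma=s) for s in sigmas]
    return [KernelSpec(family)]
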