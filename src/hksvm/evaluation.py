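"""SVM training on precomputed Grams and repeated cross-validated AUC.

The evaluation protocol is the one standardly used for small-n
expression cohorts: stratified 5-fold cross-validation repeated 10 times,
with one ROC-AUC per repetition computed from the pooled out-of-fold
decision scores, summarised as mean +/- sd over repetitions.

The SVM itself is the classical soft-margin dual; solving it is delegated
to scikit-learn's SVC in precomputed-kernel mode, and the fitted model is
exposed through the dual contract: non-negative dual coefficients a_i with
sum_i a_i y_i = 0, and decision score sum_i a_i y_i K(x_i, x) + b for a new
sample x.  ROC and AUC are computed from first principles (threshold sweep
+ trapezoid), which with tie-grouping equals the Mann-Whitney statistic
(#{pos > neg} + 1/2 #{pos = neg}) / (#pos * #neg).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .expression import ExpressionMatrix
from .kernels import CrossGram, GramMatrix, KernelSpec, gram_matrix
from .normalize import normalize

logger = logging.getLogger(__name__)

__all__ = [
    "SVMModel",
    "ConfusionCounts",
    "CVConfig",
    "CVResult",
    "validate_labels",
    "train_svm",
    "decision_scores",
    "roc_points",
    "auc",
    "confusion_counts",
    "kfold_indices",
    "cross_validate",
    "sweep_alpha",
    "sweep_sigma",
    "default_alpha_grid",
    "DEFAULT_SIGMA_GRID",
    "write_cv_table",
]

DEFAULT_SIGMA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


def default_alpha_grid() -> np.ndarray:
    """The standard exponent sweep: 0.1, 0.2, ..., 4.9 (open interval (0, 5))."""
    return np.round(np.arange(1, 50) * 0.1, 10)


def validate_labels(y: np.ndarray, require_both: bool = True) -> np.ndarray:
    y = np.asarray(y, dtype=int).ravel()
    bad = set(np.unique(y)) - {-1, 1}
    if bad:
        raise ValueError(f"labels must be -1 or +1, found {sorted(bad)}")
    if require_both and len(np.unique(y)) < 2:
        raise ValueError("both classes (-1 and +1) must be present")
    return y


# ---------------------------------------------------------------------------
# SVM on precomputed Grams


@dataclass(frozen=True)
class SVMModel:
    """Fitted soft-margin SVM in dual form over a training Gram.

    ``dual_coef[i] >= 0`` is the dual weight of training sample ``i`` (zero
    off the support), ``labels[i]`` its class, and ``bias`` the intercept;
    the decision score for a cross-Gram row k is ``k @ (dual_coef * labels)
    + bias``, with positive scores favouring class +1.
    """

    dual_coef: np.ndarray
    bias: float
    labels: np.ndarray
    C: float

    @property
    def n_train(self) -> int:
        return self.dual_coef.shape[0]


def train_svm(gram_train: GramMatrix | np.ndarray, y: np.ndarray, C: float = 1.0) -> SVMModel:
    """Fit the dual SVM on a precomputed training Gram.

    Requires both classes present and ``C > 0``; the returned model
    satisfies ``0 <= a_i <= C`` and ``sum_i a_i y_i = 0`` up to solver
    tolerance.
    """
    K = gram_train.values if isinstance(gram_train, GramMatrix) else np.asarray(gram_train, float)
    y = validate_labels(y)
    if K.shape[0] != K.shape[1] or K.shape[0] != y.shape[0]:
        raise ValueError(f"Gram shape {K.shape} does not match {y.shape[0]} labels")
    if not C > 0:
        raise ValueError("C must be > 0")
    svc = SVC(C=C, kernel="precomputed")
    svc.fit(K, y)
    if svc.fit_status_ != 0:  # pragma: no cover - libsvm rarely reports failure
        raise RuntimeError(f"SVM solver did not converge (fit_status={svc.fit_status_})")
    signed = np.zeros(y.shape[0])
    signed[svc.support_] = svc.dual_coef_[0]  # = a_i * y_i on the support
    alpha = signed * y  # a_i >= 0
    # svc.classes_ is sorted (-1, +1), so decision_function sign favours +1
    return SVMModel(alpha, float(svc.intercept_[0]), y, float(C))


def decision_scores(model: SVMModel, cross: CrossGram | np.ndarray) -> np.ndarray:
    """Continuous decision values for held-out samples."""
    V = cross.values if isinstance(cross, CrossGram) else np.asarray(cross, dtype=float)
    if V.ndim == 1:
        V = V[None, :]
    if V.shape[1] != model.n_train:
        raise ValueError(
            f"cross-Gram has {V.shape[1]} columns but the model was trained on "
            f"{model.n_train} samples"
        )
    return V @ (model.dual_coef * model.labels) + model.bias


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table at a fixed decision threshold."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.tn + self.fp)


def confusion_counts(scores: np.ndarray, y: np.ndarray, threshold: float = 0.0) -> ConfusionCounts:
    y = validate_labels(y)
    scores = np.asarray(scores, dtype=float).ravel()
    pred_pos = scores > threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & pos)),
        fn=int(np.sum(~pred_pos & pos)),
        fp=int(np.sum(pred_pos & ~pos)),
        tn=int(np.sum(~pred_pos & ~pos)),
    )


def roc_points(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ROC curve swept over all score thresholds.

    Returns an array of (FPR, TPR) points from (0, 0) to (1, 1), both
    coordinates non-decreasing.  Tied scores are grouped into a single
    step, so the trapezoidal area credits ties with 1/2.
    """
    y = validate_labels(y)
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            tp += int(y_sorted[j] == 1)
            fp += int(y_sorted[j] == -1)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return np.asarray(points)


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration.

    Equal to the Mann-Whitney statistic: the probability a random positive
    outscores a random negative, ties counted 1/2.
    """
    pts = roc_points(scores, y)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class CVConfig:
    """Repeated k-fold configuration.

    ``score_mode`` selects how each repetition's AUC is formed: ``pooled``
    (one AUC from all out-of-fold scores of the run; default, stable with
    small folds) or ``per_fold_mean`` (mean of per-fold AUCs).
    """

    k: int = 5
    runs: int = 10
    seed: int = 0
    stratified: bool = True
    C: float = 1.0
    score_mode: str = "pooled"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if not self.C > 0:
            raise ValueError("C must be > 0")
        if self.score_mode not in ("pooled", "per_fold_mean"):
            raise ValueError("score_mode must be 'pooled' or 'per_fold_mean'")


@dataclass(frozen=True)
class CVResult:
    """Per-run AUCs of one repeated-CV evaluation with their mean +/- sd."""

    aucs: tuple[float, ...]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.aucs, dtype=float)
        if arr.size == 0:
            raise ValueError("CVResult needs at least one AUC")
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("AUC values must lie in [0, 1]")
        object.__setattr__(self, "aucs", tuple(float(a) for a in arr))
        object.__setattr__(self, "mean", float(arr.mean()))
        object.__setattr__(self, "sd", float(arr.std(ddof=1)) if arr.size > 1 else 0.0)

    def summary(self) -> str:
        return f"{self.mean:.4f} ± {self.sd:.4f}"


def kfold_indices(
    n: int, k: int, seed: int, y: np.ndarray | None = None, stratified: bool = True
) -> list[np.ndarray]:
    """Deterministic k disjoint test-index sets with sizes differing by <= 1.

    With ``stratified`` and labels given, each class is shuffled and dealt
    round-robin with a counter running across classes, so per-fold class
    counts and overall fold sizes both differ by at most 1.  If a class has
    fewer than k members, stratification degrades to a plain shuffle with a
    logged warning.
    """
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratified and y is not None:
        y = validate_labels(y, require_both=False)
        counts = {c: int(np.sum(y == c)) for c in np.unique(y)}
        if min(counts.values()) < k:
            msg = f"a class has fewer than {k} members; falling back to unstratified folds"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        else:
            c = 0
            for cls in (-1, 1):
                idx = np.flatnonzero(y == cls)
                rng.shuffle(idx)
                for i in idx:
                    folds[c % k].append(int(i))
                    c += 1
            return [np.sort(np.asarray(f, dtype=int)) for f in folds]
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _run_seed(seed: int, run: int) -> int:
    return (int(seed) + 1_000_003 * run) % (2**31 - 1)


def cross_validate(
    X: ExpressionMatrix,
    y: np.ndarray,
    spec: KernelSpec,
    norm: str = "none",
    cfg: CVConfig = CVConfig(),
    per_fold_normalization: bool = False,
    precomputed_folds: list[list[np.ndarray]] | None = None,
) -> CVResult:
    """Repeated k-fold evaluation of one kernel on one labelled matrix.

    By default normalization is fitted on the full matrix before splitting
    (matching the usual array-processing workflow; a known train/test
    leakage caveat).  ``per_fold_normalization=True`` renormalizes train
    and test blocks independently inside each fold.

    Every kernel here is either evaluated pairwise or permutation-
    equivariant under eigenvalue clipping, so the full Gram is computed
    once per normalized matrix and train/test blocks are sliced per fold.
    """
    y = validate_labels(y)
    if X.n_samples != y.shape[0]:
        raise ValueError(f"{X.n_samples} samples but {y.shape[0]} labels")
    n = X.n_samples

    if not per_fold_normalization:
        Xn = normalize(X, norm)
        K_full = gram_matrix(spec, Xn).values

    aucs: list[float] = []
    for run in range(cfg.runs):
        if precomputed_folds is not None:
            folds = precomputed_folds[run]
        else:
            folds = kfold_indices(n, cfg.k, _run_seed(cfg.seed, run), y, cfg.stratified)
        pooled_scores = np.empty(n)
        fold_aucs: list[float] = []
        for fold_no, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            try:
                if per_fold_normalization:
                    from .kernels import cross_gram as _cross

                    Xtr = normalize(X.subset(train_idx), norm)
                    Xte = normalize(X.subset(test_idx), norm)
                    K_tr = gram_matrix(spec, Xtr).values
                    K_te = _cross(spec, Xtr, Xte).values
                else:
                    K_tr = K_full[np.ix_(train_idx, train_idx)]
                    K_te = K_full[np.ix_(test_idx, train_idx)]
                model = train_svm(K_tr, y[train_idx], cfg.C)
                scores = decision_scores(model, K_te)
            except Exception as exc:
                raise RuntimeError(f"run {run + 1}, fold {fold_no + 1}: {exc}") from exc
            pooled_scores[test_idx] = scores
            if cfg.score_mode == "per_fold_mean":
                fold_aucs.append(auc(scores, y[test_idx]))
        if cfg.score_mode == "pooled":
            aucs.append(auc(pooled_scores, y))
        else:
            aucs.append(float(np.mean(fold_aucs)))
    return CVResult(tuple(aucs))


def _shared_folds(n: int, y: np.ndarray, cfg: CVConfig) -> list[list[np.ndarray]]:
    return [
        kfold_indices(n, cfg.k, _run_seed(cfg.seed, run), y, cfg.stratified)
        for run in range(cfg.runs)
    ]


def sweep_alpha(
    X: ExpressionMatrix,
    y: np.ndarray,
    grid: np.ndarray | None = None,
    norm: str = "none",
    cfg: CVConfig = CVConfig(),
) -> list[tuple[float, CVResult]]:
    """Hadamard-kernel exponent sweep with fold partitions shared across
    the grid (paired comparison).  Default grid: 0.1 to 4.9, step 0.1."""
    grid_arr = default_alpha_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid_arr.size == 0:
        raise ValueError("alpha grid must be non-empty")
    if np.any(grid_arr == 0):
        raise ValueError("alpha grid must exclude 0")
    y = validate_labels(y)
    folds = _shared_folds(X.n_samples, y, cfg)
    return [
        (float(a), cross_validate(X, y, KernelSpec("hadamard", alpha=float(a)), norm, cfg,
                                  precomputed_folds=folds))
        for a in grid_arr
    ]


def sweep_sigma(
    X: ExpressionMatrix,
    y: np.ndarray,
    grid: np.ndarray | None = None,
    norm: str = "none",
    cfg: CVConfig = CVConfig(),
) -> list[tuple[float, CVResult]]:
    """RBF bandwidth sweep over the decade grid {1e-2, 1e-1, 1, 10, 100, 1000}
    by default, with fold partitions shared across the grid."""
    grid_arr = np.asarray(DEFAULT_SIGMA_GRID if grid is None else grid, dtype=float)
    if grid_arr.size == 0:
        raise ValueError("sigma grid must be non-empty")
    if np.any(grid_arr <= 0):
        raise ValueError("sigma grid values must be > 0")
    y = validate_labels(y)
    folds = _shared_folds(X.n_samples, y, cfg)
    return [
        (float(s), cross_validate(X, y, KernelSpec("rbf", sigma=float(s)), norm, cfg,
                                  precomputed_folds=folds))
        for s in grid_arr
    ]


def write_cv_table(
    results: list[tuple[str, float | None, CVResult]], path: str | Path
) -> None:
    """Write per-run AUCs as delimited text: kernel, parameter, run, auc,
    plus one summary row per entry in the tables' mean +/- sd layout."""
    rows = []
    for kernel, param, res in results:
        for run, a in enumerate(res.aucs, start=1):
            rows.append(
                {"kernel": kernel, "parameter": param, "run": run, "auc": f"{a:.15g}"}
            )
        rows.append(
            {"kernel": kernel, "parameter": param, "run": "mean_sd", "auc": res.summary()}
        )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)
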