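"""Expression-matrix container and delimited-text I/O.

The package-wide orientation is samples-as-rows: row ``i`` of
:class:`ExpressionMatrix` is the feature vector of sample ``i``.  Files on
disk may be stored either way (microarray matrices are commonly genes x
samples); :func:`read_expression` transposes to the canonical orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """An ``n_samples x p_features`` matrix of real intensities.

    Parameters
    ----------
    values
        Real matrix, one row per sample.  All entries must be finite.
    sample_ids, feature_ids
        Identifiers for rows and columns.  Generated as ``S1..Sn`` /
        ``F1..Fp`` when omitted.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...] = field(default=())
    feature_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expression values must be 2-D, got shape {values.shape}")
        n, p = values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite entry at sample index {bad[0]}, feature index {bad[1]}"
            )
        sample_ids = tuple(self.sample_ids) or tuple(f"S{i + 1}" for i in range(n))
        feature_ids = tuple(self.feature_ids) or tuple(f"F{j + 1}" for j in range(p))
        if len(sample_ids) != n:
            raise ValueError(f"{len(sample_ids)} sample ids for {n} samples")
        if len(feature_ids) != p:
            raise ValueError(f"{len(feature_ids)} feature ids for {p} features")
        _check_unique(sample_ids, "sample")
        _check_unique(feature_ids, "feature")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "feature_ids", feature_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """Row-subset preserving identifiers (used by CV splitting)."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[idx],
            tuple(self.sample_ids[i] for i in idx),
            self.feature_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )


def _check_unique(ids: tuple[str, ...], kind: str) -> None:
    seen: set[str] = set()
    for s in ids:
        if s in seen:
            raise ValueError(f"duplicate {kind} id: {s!r}")
        seen.add(s)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, orientation: str = "samples_rows") -> ExpressionMatrix:
    """Read a delimited expression table (one header row, one id column).

    ``orientation`` names the layout of the *file*: ``samples_rows`` (rows are
    samples) or ``features_rows`` (rows are genes/probes, columns are
    samples).  The returned matrix is always samples-as-rows.
    """
    if orientation not in ("samples_rows", "features_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty table")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in table ({exc})") from exc
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing/NaN value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if orientation == "features_rows":
        df = df.T
        values = values.T
    return ExpressionMatrix(
        values,
        tuple(str(s) for s in df.index),
        tuple(str(f) for f in df.columns),
    )


def write_expression(
    X: ExpressionMatrix, path: str | Path, orientation: str = "samples_rows"
) -> None:
    """Write an expression matrix as TSV/CSV (extension decides delimiter)."""
    path = Path(path)
    df = X.to_frame()
    if orientation == "features_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=_sep_for(path), float_format="%.15g")


def read_labels(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a two-column table (sample_id, label in {-1, +1})."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (sample_id, label), got {df.shape[1]}")
    ids = tuple(str(s) for s in df.iloc[:, 0])
    _check_unique(ids, "sample")
    y = df.iloc[:, 1].to_numpy(dtype=int)
    bad = set(np.unique(y)) - {-1, 1}
    if bad:
        raise ValueError(f"{path}: labels must be -1 or +1, found {sorted(bad)}")
    return ids, y


def write_labels(ids: Sequence[str], y: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"sample_id": list(ids), "label": np.asarray(y, dtype=int)}).to_csv(
        path, sep=_sep_for(path), index=False
    )
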