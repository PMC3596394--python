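"""Subject-level data containers and design-matrix construction.

The analysis operates on two 0/1-coded variables ``x`` and ``y`` together
with an ``n x m`` covariate design matrix ``z``.  Categorical covariates are
expanded to reference-cell (dummy) indicator columns before any model sees
them, so every fitting routine downstream works with a purely numeric
matrix.  ``m = 0`` is allowed and corresponds to the crude (unadjusted)
odds-ratio limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Dataset", "StratifiedTable", "load_dataset", "stratify", "ValidationError"]


class ValidationError(ValueError):
    """Raised when input data violate the binary-coding or shape contract."""


@dataclass
class Dataset:
    """Validated subject-level data.

    Attributes
    ----------
    x, y : ndarray of shape (n,)
        Binary variables coded exactly 0/1.
    z : ndarray of shape (n, m)
        Real covariate design matrix after categorical coding.  May have
        zero columns (no adjustment).
    covariate_names : list of str
        Unique labels for the columns of ``z``.
    frame : DataFrame, optional
        The original (complete-case) rows, retained so that categorical
        stratification can be performed on uncoded columns.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    frame: pd.DataFrame | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        self.y = np.asarray(self.y)
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.z.size == 0:
            self.z = self.z.reshape(len(self.x), 0)
        if self.z.shape[0] != len(self.x):
            self.z = self.z.T
        for name, v in (("x", self.x), ("y", self.y)):
            bad = ~np.isin(v, (0, 1))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"column '{name}' must be coded 0/1; found value "
                    f"{v[bad][0]!r} at row {row}"
                )
        self.x = self.x.astype(int)
        self.y = self.y.astype(int)
        if len(self.y) != len(self.x):
            raise ValidationError("x and y must have equal length")
        if not np.isfinite(self.z).all():
            raise ValidationError("z contains missing or non-finite values")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValidationError("covariate labels must be unique")
        if self.covariate_names and len(self.covariate_names) != self.z.shape[1]:
            raise ValidationError("covariate_names length must match z columns")
        if not self.covariate_names:
            self.covariate_names = [f"z{j}" for j in range(self.z.shape[1])]
        if self.n == 0:
            raise ValidationError("dataset is empty")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def m(self) -> int:
        return self.z.shape[1]

    @property
    def category(self) -> np.ndarray:
        """(X,Y) category index per subject: 0=(0,0), 1=(0,1), 2=(1,0), 3=(1,1)."""
        return 2 * self.x + self.y

    def cell_counts(self) -> np.ndarray:
        """Marginal 2x2 cell counts as (n00, n01, n10, n11)."""
        return np.bincount(self.category, minlength=4)

    def swapped(self) -> "Dataset":
        """The same data with the roles of X and Y exchanged."""
        return Dataset(self.y.copy(), self.x.copy(), self.z.copy(),
                       list(self.covariate_names), self.frame, self.n_dropped)

    def relabel_x(self) -> "Dataset":
        """The same data with X recoded 0 <-> 1 (inverts every odds ratio)."""
        return Dataset(1 - self.x, self.y.copy(), self.z.copy(),
                       list(self.covariate_names), self.frame, self.n_dropped)


@dataclass
class StratifiedTable:
    """Per-stratum 2x2 counts for the classical Mantel-Haenszel path.

    ``tables`` has shape (k, 4) with columns (n00, n01, n10, n11); cell
    (x, y) of stratum i is ``tables[i, 2*x + y]``.
    """

    tables: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tables = np.asarray(self.tables, dtype=int).reshape(-1, 4)
        if (self.tables < 0).any():
            raise ValidationError("stratum counts must be nonnegative")
        if not self.labels:
            self.labels = list(range(self.tables.shape[0]))

    @property
    def k(self) -> int:
        return self.tables.shape[0]

    @property
    def stratum_sizes(self) -> np.ndarray:
        return self.tables.sum(axis=1)

    def marginal(self) -> np.ndarray:
        """Collapse strata to the marginal 2x2 table (n00, n01, n10, n11)."""
        return self.tables.sum(axis=0)


def _code_covariates(
    df: pd.DataFrame,
    z_cols: Sequence[str],
    categorical: Sequence[str] = (),
    reference: dict[str, object] | None = None,
    standardize: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Expand covariates into a numeric design matrix.

    Categorical columns get reference-cell indicator coding; the reference
    level is the lexicographically first unless overridden via ``reference``.
    """
    reference = reference or {}
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for col in z_cols:
        s = df[col]
        if col in categorical or not pd.api.types.is_numeric_dtype(s):
            levels = sorted(s.astype(str).unique())
            ref = str(reference.get(col, levels[0]))
            if ref not in levels:
                raise ValidationError(f"reference level {ref!r} not found in '{col}'")
            for lev in levels:
                if lev == ref:
                    continue
                blocks.append((s.astype(str) == lev).to_numpy(float)[:, None])
                names.append(f"{col}[{lev}]")
        else:
            v = s.to_numpy(float)[:, None]
            if standardize and np.std(v) > 0:
                v = (v - v.mean()) / v.std()
            blocks.append(v)
            names.append(col)
    z = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    return z, names


def load_dataset(
    path: str | Path,
    x_col: str,
    y_col: str,
    z_cols: Sequence[str] = (),
    categorical: Sequence[str] = (),
    reference: dict[str, object] | None = None,
    standardize: bool = False,
    sep: str | None = None,
) -> Dataset:
    """Read a delimited text file into a validated :class:`Dataset`.

    Rows with a missing value in any selected column are dropped
    (complete-case analysis); the number dropped is logged and stored on
    the returned object.  The delimiter is inferred from the extension
    (``.tsv`` -> tab) unless ``sep`` is given.

    Raises
    ------
    ValidationError
        If ``x_col``/``y_col`` contain values other than 0/1, or no rows
        survive complete-case filtering.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cols = [x_col, y_col, *z_cols]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"columns not found in {path.name}: {missing}")
    sub = df[cols]
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d incomplete rows out of %d", n_dropped, len(sub))
    sub = sub[keep].reset_index(drop=True)
    if sub.empty:
        raise ValidationError("no complete-case rows remain after filtering")
    for col in (x_col, y_col):
        vals = sub[col]
        bad = ~vals.isin([0, 1, "0", "1", 0.0, 1.0])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"column '{col}' must be coded 0/1; found {vals.iloc[row]!r} at row {row}"
            )
    z, names = _code_covariates(sub, z_cols, categorical, reference, standardize)
    return Dataset(
        sub[x_col].astype(int).to_numpy(),
        sub[y_col].astype(int).to_numpy(),
        z,
        names,
        frame=sub,
        n_dropped=n_dropped,
    )


def stratify(data: Dataset, strata_col: str | None = None) -> StratifiedTable:
    """Cross-tabulate (X, Y) within each level of a categorical column.

    With ``strata_col=None`` the subjects form a single stratum (the
    marginal table).  Levels whose table has a zero margin are retained:
    the Mantel-Haenszel sums simply receive zero contributions from them.
    """
    if strata_col is None:
        return StratifiedTable(data.cell_counts()[None, :], labels=["<all>"])
    if data.frame is None or strata_col not in data.frame.columns:
        raise ValidationError(f"stratum column '{strata_col}' not available")
    levels = data.frame[strata_col].astype(str)
    cat = data.category
    labels = sorted(levels.unique())
    tables = np.zeros((len(labels), 4), dtype=int)
    for i, lev in enumerate(labels):
        tables[i] = np.bincount(cat[(levels == lev).to_numpy()], minlength=4)
    return StratifiedTable(tables, labels=labels)
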