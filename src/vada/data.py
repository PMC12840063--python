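"""Longitudinal data container and long-format table I/O.

Data are N subjects observed at L common time points (or locations) on a
univariate outcome and P covariates.  Covariates and the outcome may be
real-valued or categorical; categorical covariates are expanded one-hot
for encoder input while the container keeps per-feature bookkeeping so
decoders can emit one simplex head per categorical feature.

The on-disk format is a delimited long table (comma or tab, header
required) with columns ``subject_id``, ``time_index`` (1-based), ``y``
and one column per covariate.  A schema mapping declares which covariate
columns (and optionally the outcome) are categorical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["FeatureKind", "LongitudinalDataset", "read_long_table", "write_long_table"]


@dataclass(frozen=True)
class FeatureKind:
    """Tag for one covariate column: continuous, or categorical with G levels."""

    name: str
    categories: tuple | None = None  # None => continuous

    @property
    def is_categorical(self) -> bool:
        return self.categories is not None

    @property
    def n_levels(self) -> int:
        return 0 if self.categories is None else len(self.categories)


@dataclass
class LongitudinalDataset:
    """N subjects x L measurements of mixed-type covariates plus outcomes.

    ``X`` holds the one-hot expanded covariate array (N, L, P_expanded);
    ``feature_kinds`` records the original columns in order so the
    expansion is invertible.  ``y`` is (N, L): floats for a real outcome,
    integer category indices for a categorical outcome.  Ground-truth
    fields are populated only by the simulators.
    """

    subject_ids: np.ndarray          # (N,)
    X: np.ndarray                    # (N, L, P_expanded) float
    feature_kinds: list[FeatureKind]
    y: np.ndarray                    # (N, L)
    outcome_kind: str = "real"       # "real" | "categorical"
    outcome_categories: tuple | None = None
    c_true: np.ndarray | None = None       # (N,)
    Z_true: np.ndarray | None = None       # (N, L, D_true)
    u_true: np.ndarray | None = None       # (N, L)

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        X = np.asarray(self.X)
        self.X = X if X.dtype.kind == "f" else X.astype(float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 3:
            raise ValueError("X must have shape (N, L, P)")
        n, l, p = self.X.shape
        if l < 1 or p < 1:
            raise ValueError("L and P must be >= 1")
        if self.y.shape != (n, l):
            raise ValueError(f"y shape {self.y.shape} does not match X {(n, l)}")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must equal N")
        if not np.isfinite(self.X).all():
            raise ValueError("covariates contain non-finite or missing values")
        if self.expanded_width != p:
            raise ValueError("feature_kinds are inconsistent with X width")
        if self.outcome_kind == "categorical":
            g = len(self.outcome_categories or ())
            yi = self.y.astype(int)
            if not ((yi >= 0) & (yi < g)).all():
                raise ValueError("categorical outcome index out of declared range")
        elif not np.isfinite(self.y.astype(float)).all():
            raise ValueError("outcome contains non-finite or missing values")

    # -- derived sizes --------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_measurements(self) -> int:
        return self.X.shape[1]

    @property
    def expanded_width(self) -> int:
        return sum(k.n_levels if k.is_categorical else 1 for k in self.feature_kinds)

    @property
    def continuous_slices(self) -> list[int]:
        """Expanded-column indices of continuous features, in feature order."""
        cols, j = [], 0
        for k in self.feature_kinds:
            if k.is_categorical:
                j += k.n_levels
            else:
                cols.append(j)
                j += 1
        return cols

    @property
    def categorical_blocks(self) -> list[tuple[int, int]]:
        """(start, n_levels) expanded-column blocks of categorical features."""
        blocks, j = [], 0
        for k in self.feature_kinds:
            if k.is_categorical:
                blocks.append((j, k.n_levels))
                j += k.n_levels
            else:
                j += 1
        return blocks

    def subset(self, idx) -> "LongitudinalDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            subject_ids=self.subject_ids[idx],
            X=self.X[idx],
            y=self.y[idx],
            c_true=None if self.c_true is None else self.c_true[idx],
            Z_true=None if self.Z_true is None else self.Z_true[idx],
            u_true=None if self.u_true is None else self.u_true[idx],
        )


def _one_hot(codes: np.ndarray, g: int) -> np.ndarray:
    out = np.zeros(codes.shape + (g,))
    out[(*np.indices(codes.shape), codes)] = 1.0
    return out


def read_long_table(path, categorical: dict | None = None,
                    outcome_categorical: bool = False) -> LongitudinalDataset:
    """Read a long-format delimited table into a :class:`LongitudinalDataset`.

    Parameters
    ----------
    path : str or file-like
        Comma- or tab-delimited file with header columns ``subject_id``,
        ``time_index``, ``y`` and covariate columns.
    categorical : dict, optional
        Maps covariate column name -> list of levels, or ``None`` to infer
        levels in order of first appearance.
    outcome_categorical : bool
        Treat the outcome column as categorical.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "time_index", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"long table must contain columns {sorted(required)}")
    if df[["subject_id", "time_index", "y"]].isna().any().any() or df.isna().any().any():
        raise ValueError("missing values are not supported")
    categorical = dict(categorical or {})

    subjects = pd.unique(df["subject_id"])
    times = np.sort(pd.unique(df["time_index"]))
    L = len(times)
    if not np.array_equal(times, np.arange(1, L + 1)):
        raise ValueError("time_index must cover 1..L for every subject")
    counts = df.groupby("subject_id", sort=False).size()
    if not (counts == L).all():
        raise ValueError("every subject must have exactly L measurements")

    df = df.sort_values(["subject_id", "time_index"],
                        key=lambda s: s.map({v: i for i, v in enumerate(subjects)})
                        if s.name == "subject_id" else s)
    cov_cols = [c for c in df.columns if c not in required]
    n = len(subjects)

    kinds, mats = [], []
    for c in cov_cols:
        vals = df[c].to_numpy()
        if c in categorical:
            levels = categorical[c]
            if levels is None:
                levels = list(pd.unique(df[c]))  # order of first appearance
            lut = {v: i for i, v in enumerate(levels)}
            try:
                codes = np.array([lut[v] for v in vals])
            except KeyError as e:
                raise ValueError(f"column {c!r}: value {e.args[0]!r} outside declared levels")
            kinds.append(FeatureKind(c, tuple(levels)))
            mats.append(_one_hot(codes.reshape(n, L), len(levels)))
        else:
            kinds.append(FeatureKind(c))
            mats.append(vals.astype(float).reshape(n, L, 1))
    X = np.concatenate(mats, axis=2) if mats else np.zeros((n, L, 0))

    yv = df["y"].to_numpy()
    if outcome_categorical:
        levels = list(pd.unique(df["y"]))
        lut = {v: i for i, v in enumerate(levels)}
        y = np.array([lut[v] for v in yv]).reshape(n, L)
        return LongitudinalDataset(subjects, X, kinds, y, outcome_kind="categorical",
                                   outcome_categories=tuple(levels))
    return LongitudinalDataset(subjects, X, kinds, yv.astype(float).reshape(n, L))


def write_long_table(dataset: LongitudinalDataset, path, sep: str = "\t") -> None:
    """Write the dataset back to the long-format dialect (one-hot collapsed)."""
    n, L = dataset.n_subjects, dataset.n_measurements
    cols = {
        "subject_id": np.repeat(dataset.subject_ids, L),
        "time_index": np.tile(np.arange(1, L + 1), n),
    }
    if dataset.outcome_kind == "categorical":
        cats = np.asarray(dataset.outcome_categories, dtype=object)
        cols["y"] = cats[dataset.y.astype(int).reshape(-1)]
    else:
        cols["y"] = dataset.y.reshape(-1)
    j = 0
    for k in dataset.feature_kinds:
        if k.is_categorical:
            block = dataset.X[:, :, j:j + k.n_levels].reshape(n * L, k.n_levels)
            cats = np.asarray(k.categories, dtype=object)
            cols[k.name] = cats[block.argmax(axis=1)]
            j += k.n_levels
        else:
            cols[k.name] = dataset.X[:, :, j].reshape(-1)
            j += 1
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
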