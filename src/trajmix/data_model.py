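"""Domain containers for longitudinal trajectory data and design matrices.

Data are long-format: one row per measurement (subject id, time, response).
Internally a dataset keeps per-subject ragged arrays plus a stacked view
(`y_stack`, `subject_index`) used by the vectorized EM routines.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalDataset",
    "DesignSpec",
    "DesignMatrices",
    "read_long_csv",
    "build_design",
]


class FormatError(ValueError):
    """Input file does not conform to the expected long-format layout."""


@dataclass
class LongitudinalDataset:
    """Longitudinal measurements for n subjects.

    Subject i contributes a response vector y_i of length p_i observed at
    times t_i; all p_i measurements of one subject belong to the same latent
    trajectory group. Within-subject order is preserved as given (no sorting
    by time is imposed).
    """

    subject_ids: list
    times: list[np.ndarray]
    responses: list[np.ndarray]
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        self.responses = [np.asarray(y, dtype=float) for y in self.responses]
        if not (len(self.subject_ids) == len(self.times) == len(self.responses)):
            raise ValueError("subject_ids, times and responses must have equal length")
        for i, (t, y) in enumerate(zip(self.times, self.responses)):
            if len(y) < 1:
                raise ValueError(f"subject {self.subject_ids[i]!r} has no measurements")
            if len(t) != len(y):
                raise ValueError(f"subject {self.subject_ids[i]!r}: times/responses length mismatch")
            if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
                raise ValueError(f"subject {self.subject_ids[i]!r}: non-finite time or response")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=int)
            if len(self.true_labels) != self.n:
                raise ValueError("true_labels must have one entry per subject")

    @property
    def n(self) -> int:
        """Number of subjects."""
        return len(self.subject_ids)

    @property
    def p(self) -> np.ndarray:
        """Per-subject measurement counts p_i."""
        return np.array([len(y) for y in self.responses], dtype=int)

    @property
    def n_total(self) -> int:
        """Total number of measurements N = sum_i p_i."""
        return int(self.p.sum())

    # -- stacked views (cached) ------------------------------------------
    @property
    def y_stack(self) -> np.ndarray:
        return np.concatenate(self.responses)

    @property
    def t_stack(self) -> np.ndarray:
        return np.concatenate(self.times)

    @property
    def subject_index(self) -> np.ndarray:
        """Length-N integer array mapping each stacked row to its subject."""
        return np.repeat(np.arange(self.n), self.p)

    def with_responses(self, y_stack: np.ndarray) -> "LongitudinalDataset":
        """Copy of the dataset with responses replaced from a stacked array."""
        y_stack = np.asarray(y_stack, dtype=float)
        if y_stack.shape != (self.n_total,):
            raise ValueError("replacement responses must match N")
        splits = np.cumsum(self.p)[:-1]
        return LongitudinalDataset(
            subject_ids=list(self.subject_ids),
            times=[t.copy() for t in self.times],
            responses=list(np.split(y_stack, splits)),
            true_labels=None if self.true_labels is None else self.true_labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns id, time, y (and true_label if set)."""
        df = pd.DataFrame(
            {
                "id": np.repeat(np.asarray(self.subject_ids, dtype=object), self.p),
                "time": self.t_stack,
                "y": self.y_stack,
            }
        )
        if self.true_labels is not None:
            df["true_label"] = np.repeat(self.true_labels, self.p)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DesignSpec:
    """Rule mapping a vector of times to a design matrix.

    kinds:
      * ``polynomial(degree d)`` -> columns [1, t, ..., t^d], q = d+1
      * ``broken_stick(knot)``   -> columns [1, t, (t-knot)_+], q = 3
      * ``custom(builder, q)``   -> user column-builder t -> (len(t), q)
    """

    kind: str
    degree: int | None = None
    knot: float | None = None
    builder: Callable[[np.ndarray], np.ndarray] | None = None
    q_custom: int | None = None

    @classmethod
    def polynomial(cls, degree: int) -> "DesignSpec":
        if degree < 0:
            raise ValueError("polynomial degree must be >= 0")
        return cls(kind="polynomial", degree=int(degree))

    @classmethod
    def broken_stick(cls, knot: float) -> "DesignSpec":
        return cls(kind="broken_stick", knot=float(knot))

    @classmethod
    def custom(cls, builder: Callable[[np.ndarray], np.ndarray], q: int) -> "DesignSpec":
        return cls(kind="custom", builder=builder, q_custom=int(q))

    @property
    def q(self) -> int:
        if self.kind == "polynomial":
            return self.degree + 1
        if self.kind == "broken_stick":
            return 3
        if self.kind == "custom":
            return self.q_custom
        raise ValueError(f"unknown design kind {self.kind!r}")

    def rows(self, t: np.ndarray) -> np.ndarray:
        """Design rows for a vector of times; shape (len(t), q)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "polynomial":
            return np.vander(t, N=self.degree + 1, increasing=True)
        if self.kind == "broken_stick":
            return np.column_stack([np.ones_like(t), t, np.maximum(t - self.knot, 0.0)])
        if self.kind == "custom":
            X = np.asarray(self.builder(t), dtype=float)
            if X.shape != (len(t), self.q_custom):
                raise ValueError("custom builder returned wrong shape")
            return X
        raise ValueError(f"unknown design kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind == "polynomial":
            return f"poly:{self.degree}"
        if self.kind == "broken_stick":
            return f"bs:{self.knot:g}"
        return "custom"


@dataclass
class DesignMatrices:
    """Per-subject design matrices X_i (p_i x q), aligned to a dataset."""

    matrices: list[np.ndarray]
    spec: DesignSpec

    @property
    def q(self) -> int:
        return self.spec.q

    @property
    def X_stack(self) -> np.ndarray:
        return np.vstack(self.matrices)


def read_long_csv(
    path: str | Path | io.IOBase,
    id_col: str = "id",
    time_col: str = "time",
    y_col: str = "y",
    label_col: str | None = None,
) -> LongitudinalDataset:
    """Read long-format CSV (one row per measurement) into a dataset.

    Rows are grouped by id preserving within-id file order. Raises
    :class:`FormatError` on missing columns and a parse error naming the
    first offending row for non-numeric times/responses.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError("input file contains no data rows")
    for col in [id_col, time_col, y_col] + ([label_col] if label_col else []):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}; found {list(df.columns)}")
    for col in (time_col, y_col):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"non-numeric or missing value in column {col!r} at data row {row}")
        df[col] = vals.astype(float)

    ids, times, responses, labels = [], [], [], []
    for sid, g in df.groupby(id_col, sort=False):
        ids.append(sid)
        times.append(g[time_col].to_numpy())
        responses.append(g[y_col].to_numpy())
        if label_col:
            lab = g[label_col].unique()
            if len(lab) != 1:
                raise FormatError(f"subject {sid!r} has inconsistent labels")
            labels.append(int(lab[0]))
    return LongitudinalDataset(
        subject_ids=ids,
        times=times,
        responses=responses,
        true_labels=np.array(labels, dtype=int) if label_col else None,
    )


def build_design(data: LongitudinalDataset, spec: DesignSpec) -> DesignMatrices:
    """Construct per-subject design matrices from a spec.

    Deterministic and independent of subject order. A broken-stick knot
    outside the observed time range is legal (warning only) but yields a
    degenerate or collinear hinge column.
    """
    if spec.kind == "broken_stick":
        t = data.t_stack
        if not (t.min() <= spec.knot <= t.max()):
            warnings.warn(
                f"broken-stick knot {spec.knot:g} lies outside the observed time "
                f"range [{t.min():g}, {t.max():g}]; the hinge column is degenerate",
                UserWarning,
                stacklevel=2,
            )
    return DesignMatrices(matrices=[spec.rows(t) for t in data.times], spec=spec)
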