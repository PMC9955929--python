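"""Reading and writing sample-by-feature matrices, labels and selection reports.

All downstream modules consume the domain containers defined here:
:class:`FeatureMatrix` (samples in rows, features in columns),
:class:`LabelVector` (one categorical label per sample) and
:class:`SelectionReport` (an ordered, named feature subset with its
selection trace summary).

Matrices travel as CSV/TSV with a header row and one designated label
column. Loading is strict: missing values, non-numeric feature cells and
duplicate feature names abort with a descriptive error rather than being
silently repaired — this selector has no missing-data model, and silent
imputation would change results invisibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataFormatError",
    "ConfigurationError",
    "FeatureMatrix",
    "LabelVector",
    "SelectedFeature",
    "SelectionReport",
    "read_matrix",
    "write_matrix",
    "read_report",
    "write_report",
    "write_ranked_list",
]


class DataFormatError(ValueError):
    """Raised when an input file violates the expected tabular contract."""


class ConfigurationError(ValueError):
    """Raised when user-supplied options are inconsistent or out of range."""


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = {n for n in names if n in seen or seen.add(n)}  # type: ignore[func-returns-value]
    if dups:
        raise DataFormatError(f"duplicate {what}: {sorted(dups)}")


@dataclass
class FeatureMatrix:
    """An n x m numeric matrix with named features and sample ids.

    Rows are samples, columns are features. Values must be finite floats;
    construction fails loudly on NaN/inf, on fewer than two samples, and on
    duplicate feature names or sample ids.
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataFormatError("feature matrix must be 2-dimensional")
        n, m = self.values.shape
        if n < 2:
            raise DataFormatError(f"need at least 2 samples, got {n}")
        if m < 1:
            raise DataFormatError("need at least 1 feature")
        self.feature_names = [str(f) for f in self.feature_names]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_names) != m:
            raise DataFormatError(
                f"{len(self.feature_names)} feature names for {m} columns"
            )
        if len(self.sample_ids) != n:
            raise DataFormatError(f"{len(self.sample_ids)} sample ids for {n} rows")
        _check_unique(self.feature_names, "feature names")
        _check_unique(self.sample_ids, "sample ids")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataFormatError(
                "non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_names[bad[1]]!r}; "
                "missing/inf entries are refused (no imputation model)"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        """Return a new matrix restricted to ``names`` (in the given order)."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], list(names), list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=self.feature_names, index=self.sample_ids
        )


@dataclass
class LabelVector:
    """Per-sample categorical labels with the ordered class set and priors."""

    labels: np.ndarray
    classes: list = field(default_factory=list)
    priors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not self.classes:
            self.classes = sorted(set(self.labels.tolist()))
        unknown = set(self.labels.tolist()) - set(self.classes)
        if unknown:
            raise DataFormatError(f"labels outside the class set: {sorted(unknown)}")
        if len(self.classes) < 2:
            raise DataFormatError("need at least 2 classes")
        if self.priors is None:
            counts = np.array([(self.labels == c).sum() for c in self.classes])
            self.priors = counts / counts.sum()
        self.priors = np.asarray(self.priors, dtype=float)
        if abs(self.priors.sum() - 1.0) > 1e-12:
            raise DataFormatError("class priors must sum to 1")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def __len__(self) -> int:
        return len(self.labels)

    def class_indices(self) -> np.ndarray:
        """Labels encoded as integer indices into ``classes``."""
        lookup = {c: i for i, c in enumerate(self.classes)}
        return np.array([lookup[v] for v in self.labels.tolist()])

    def subset(self, rows: Sequence[int]) -> "LabelVector":
        return LabelVector(self.labels[list(rows)], classes=list(self.classes))


@dataclass
class SelectedFeature:
    name: str
    weight: float
    redundancy: float
    criterion: float


@dataclass
class SelectionReport:
    """Ordered result of a feature-selection run, with provenance."""

    method: str
    alpha: float
    k: int
    selected: list[SelectedFeature]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0,1], got {self.alpha}")
        if self.k < 1:
            raise ConfigurationError(f"k must be a positive integer, got {self.k}")
        if len(self.selected) != self.k:
            raise ConfigurationError(
                f"report lists {len(self.selected)} features but k={self.k}"
            )
        names = [s.name for s in self.selected]
        _check_unique(names, "selected feature names")

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.selected]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "k": self.k,
            "selected": [
                {
                    "feature_name": s.name,
                    "weight": s.weight,
                    "redundancy": s.redundancy,
                    "criterion": s.criterion,
                }
                for s in self.selected
            ],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionReport":
        return cls(
            method=d["method"],
            alpha=d["alpha"],
            k=d["k"],
            selected=[
                SelectedFeature(
                    e["feature_name"], e["weight"], e["redundancy"], e["criterion"]
                )
                for e in d["selected"]
            ],
            provenance=d.get("provenance", {}),
        )


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_matrix(
    path: str | Path,
    label_column: str = "class",
    delimiter: str | None = None,
) -> tuple[FeatureMatrix, LabelVector]:
    """Load a CSV/TSV into a (FeatureMatrix, LabelVector) pair.

    The file must have a header row; ``label_column`` names the class
    column, every other column is a feature. Column order is preserved and
    no row is ever dropped. Delimiter defaults to comma, or tab for
    ``.tsv``/``.tab`` files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _delimiter_for(path, delimiter)
    import csv as _csv

    with open(path, encoding="utf-8", newline="") as fh:
        header = next(_csv.reader(fh, delimiter=sep), None)
    if not header:
        raise DataFormatError("empty file or missing header row")
    _check_unique(header, "column names")  # pandas would silently mangle these
    df = pd.read_csv(path, sep=sep, header=0, dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not in header {list(df.columns)}"
        )
    feature_cols = [c for c in df.columns if c != label_column]
    if not feature_cols:
        raise DataFormatError("no feature columns besides the label column")
    _check_unique(list(df.columns), "column names")
    labels = df[label_column].to_numpy()
    if (labels == "").any():
        row = int(np.argmax(labels == ""))
        raise DataFormatError(f"missing label in data row {row}")
    values = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        raw = df[col].to_numpy()
        try:
            values[:, j] = raw.astype(float)
        except ValueError:
            for i, cell in enumerate(raw):
                try:
                    float(cell)
                except ValueError:
                    raise DataFormatError(
                        f"non-numeric value {cell!r} in column {col!r}, data row {i}"
                    ) from None
            raise
    fm = FeatureMatrix(values, feature_cols, [str(i) for i in range(len(df))])
    lv = LabelVector(labels)
    return fm, lv


def write_matrix(
    X: FeatureMatrix,
    y: LabelVector,
    path: str | Path,
    label_column: str = "class",
    delimiter: str | None = None,
) -> None:
    """Write a matrix + labels as CSV/TSV, round-trippable bit-exactly.

    Floats are rendered with ``repr`` (shortest round-trip form), so
    ``read_matrix(write_matrix(...))`` reproduces finite doubles exactly.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    if label_column in X.feature_names:
        raise ConfigurationError(
            f"label column name {label_column!r} collides with a feature name"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(sep.join([*X.feature_names, label_column]) + "\n")
        for i in range(X.n_samples):
            cells = [repr(v) for v in X.values[i].tolist()]
            cells.append(str(y.labels[i]))
            fh.write(sep.join(cells) + "\n")


def write_report(report: SelectionReport, path: str | Path) -> None:
    """Serialize a selection report as JSON (lossless via ``read_report``)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> SelectionReport:
    with open(path, encoding="utf-8") as fh:
        return SelectionReport.from_dict(json.load(fh))


def write_ranked_list(report: SelectionReport, path: str | Path) -> None:
    """Plain-text ranked feature list, one name per line, for shell pipelines."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in report.selected:
            fh.write(s.name + "\n")
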