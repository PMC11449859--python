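"""Dataset and prediction I/O, plus the black-box predictor contract.

A dataset is a dense ``n_instances x series_length`` matrix of real values
(one univariate series per row) with optional class labels. Supported on-disk
formats are plain CSV/TSV (one series per row, optional ``id`` and ``label``
columns, optional header) and the UCR-style ``.ts`` dialect
(``@problemName`` / ``@univariate`` / ``@classLabel`` / ``@data`` with a
colon-separated label suffix per line).

The black-box model being explained is only ever seen through
:class:`BlackBoxPredictor`: series in, class label out. Predictions may also
come from a file, so the explainer runs without any live model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    ConfigError,
    EmptyInputError,
    ParseError,
    UnequalLengthError,
)

__all__ = [
    "TimeSeriesDataset",
    "BlackBoxPredictor",
    "PredictionSet",
    "read_dataset",
    "write_dataset",
    "load_predictions",
]


def _coerce_label(token: str):
    """Parse a label token: int if possible, else float, else the raw string."""
    token = token.strip()
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError:
        return token


@dataclass
class TimeSeriesDataset:
    """A labeled (or unlabeled) collection of equal-length univariate series.

    Time indexing is 0-based throughout: a series of length ``n`` has time
    steps ``0 .. n-1``.
    """

    values: np.ndarray
    labels: list | None = None
    instance_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError(
                f"values must be a 2-d matrix, got ndim={self.values.ndim} "
                "(multivariate input is not supported)"
            )
        if self.values.shape[0] == 0:
            raise EmptyInputError("dataset has no instances")
        if self.values.shape[1] < 2:
            raise ConfigError(
                f"series_length must be >= 2, got {self.values.shape[1]}"
            )
        if np.isnan(self.values).any():
            raise ParseError("dataset contains missing values; imputation is not performed")
        if not self.instance_ids:
            self.instance_ids = [str(i) for i in range(self.values.shape[0])]
        if len(self.instance_ids) != self.values.shape[0]:
            raise AlignmentError(
                f"{len(self.instance_ids)} instance ids for {self.values.shape[0]} rows"
            )
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise AlignmentError(
                    f"{len(self.labels)} labels for {self.values.shape[0]} rows"
                )

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def series_length(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeSeriesDataset):
            return NotImplemented
        if self.values.shape != other.values.shape:
            return False
        return (
            bool(np.allclose(self.values, other.values, rtol=0, atol=1e-12))
            and self.labels == other.labels
            and self.instance_ids == other.instance_ids
        )


@dataclass
class BlackBoxPredictor:
    """The opaque prediction contract: one class label per input series.

    ``predict_fn`` maps an ``(n, length)`` array to ``n`` labels. The wrapper
    checks that returned labels stay inside ``classes`` — the explainer never
    assumes anything else about the model.
    """

    predict_fn: Callable[[np.ndarray], Sequence]
    classes: tuple

    def predict(self, X) -> list:
        if isinstance(X, TimeSeriesDataset):
            X = X.values
        X = np.atleast_2d(np.asarray(X, dtype=float))
        labels = list(self.predict_fn(X))
        if len(labels) != X.shape[0]:
            raise AlignmentError(
                f"predictor returned {len(labels)} labels for {X.shape[0]} series"
            )
        bad = [l for l in labels if l not in self.classes]
        if bad:
            raise AlignmentError(f"predictor returned labels outside its classes: {bad[:5]}")
        return labels


@dataclass
class PredictionSet:
    """Black-box labels aligned to dataset rows."""

    labels: list
    source: str = "live_predictor"  # or "file"

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if self.source not in ("live_predictor", "file"):
            raise ConfigError(f"unknown prediction source {self.source!r}")

    def __len__(self) -> int:
        return len(self.labels)


def predict_dataset(predictor: BlackBoxPredictor, ds: TimeSeriesDataset) -> PredictionSet:
    """Run a live predictor over a dataset, returning an aligned PredictionSet."""
    return PredictionSet(labels=predictor.predict(ds), source="live_predictor")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DELIMS = {"csv": ",", "tsv": "\t"}


def _detect_format(path: str, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in ("csv", "tsv", "ts"):
            raise ConfigError(f"unknown format {fmt!r}")
        return fmt
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("csv", "tsv", "ts"):
        return ext
    if ext in ("txt", "tab"):
        return "tsv"
    raise ConfigError(f"cannot auto-detect format from extension of {path!r}")


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_delimited(path: str, delim: str) -> TimeSeriesDataset:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path} is empty")
    rows = [ln.split(delim) for ln in lines]

    header = rows[0]
    has_header = any(not _is_float(tok) for tok in header)
    id_col = label_col = None
    if has_header:
        names = [tok.strip().lower() for tok in header]
        if "id" in names:
            id_col = names.index("id")
        if "label" in names:
            label_col = names.index("label")
        data_rows = rows[1:]
        if not data_rows:
            raise EmptyInputError(f"{path} has a header but no data rows")
        ncols = len(header)
    else:
        data_rows = rows
        ncols = len(rows[0])

    widths = {len(r) for r in data_rows}
    if len(widths) > 1 or (has_header and widths != {ncols}):
        raise UnequalLengthError(
            f"{path}: rows have differing column counts {sorted(widths)}"
        )

    value_cols = [j for j in range(ncols) if j not in (id_col, label_col)]
    values = np.empty((len(data_rows), len(value_cols)), dtype=float)
    for i, row in enumerate(data_rows):
        for jj, j in enumerate(value_cols):
            tok = row[j].strip()
            if not _is_float(tok):
                raise ParseError(f"{path}: non-numeric cell {tok!r} at row {i}, column {j}")
            values[i, jj] = float(tok)

    ids = [row[id_col].strip() for row in data_rows] if id_col is not None else []
    labels = [_coerce_label(row[label_col]) for row in data_rows] if label_col is not None else None
    return TimeSeriesDataset(values=values, labels=labels, instance_ids=ids)


def _read_ts(path: str) -> TimeSeriesDataset:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path} is empty")
    has_labels = False
    data_start = None
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            continue
        if ln.lower().startswith("@classlabel"):
            has_labels = ln.split()[1].lower() == "true"
        elif ln.lower().startswith("@univariate"):
            if ln.split()[1].lower() != "true":
                raise ConfigError(f"{path}: multivariate .ts files are not supported")
        elif ln.lower().startswith("@data"):
            data_start = i + 1
            break
    if data_start is None:
        raise ParseError(f"{path}: no @data section")
    data_lines = [ln for ln in lines[data_start:] if not ln.startswith("#")]
    if not data_lines:
        raise EmptyInputError(f"{path}: @data section is empty")

    series, labels = [], []
    for i, ln in enumerate(data_lines):
        parts = ln.split(":")
        if has_labels:
            if len(parts) == 1:
                raise ParseError(f"{path}: data line {i} lacks the class-label suffix")
            if len(parts) > 2:
                raise ConfigError(f"{path}: multivariate .ts files are not supported")
            body, label = parts
            labels.append(_coerce_label(label))
        else:
            if len(parts) > 1:
                raise ConfigError(f"{path}: multivariate .ts files are not supported")
            body = parts[0]
        toks = [t.strip() for t in body.split(",")]
        for t in toks:
            if not _is_float(t):
                raise ParseError(f"{path}: non-numeric value {t!r} on data line {i}")
        series.append([float(t) for t in toks])

    widths = {len(s) for s in series}
    if len(widths) > 1:
        raise UnequalLengthError(f"{path}: series have differing lengths {sorted(widths)}")
    return TimeSeriesDataset(
        values=np.asarray(series, dtype=float),
        labels=labels if has_labels else None,
    )


def read_dataset(path: str, format: str = "auto") -> TimeSeriesDataset:
    """Read a time-series dataset from CSV/TSV or UCR-style ``.ts``."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "ts":
        return _read_ts(path)
    return _read_delimited(path, _DELIMS[fmt])


def write_dataset(ds: TimeSeriesDataset, path: str, format: str = "auto") -> None:
    """Write a dataset so that ``read_dataset`` round-trips it bit-exactly."""
    fmt = _detect_format(path, format)
    if fmt == "ts":
        with open(path, "w") as fh:
            fh.write(f"@problemName {os.path.splitext(os.path.basename(path))[0]}\n")
            fh.write("@timeStamps false\n")
            fh.write("@univariate true\n")
            if ds.labels is not None:
                classes = sorted({str(l) for l in ds.labels})
                fh.write("@classLabel true " + " ".join(classes) + "\n")
            else:
                fh.write("@classLabel false\n")
            fh.write("@data\n")
            for i in range(ds.n_instances):
                body = ",".join(repr(float(v)) for v in ds.values[i])
                if ds.labels is not None:
                    body += f":{ds.labels[i]}"
                fh.write(body + "\n")
        return

    delim = _DELIMS[fmt]
    with open(path, "w") as fh:
        cols = ["id"]
        if ds.labels is not None:
            cols.append("label")
        cols += [f"t{j}" for j in range(ds.series_length)]
        fh.write(delim.join(cols) + "\n")
        for i in range(ds.n_instances):
            row = [ds.instance_ids[i]]
            if ds.labels is not None:
                row.append(str(ds.labels[i]))
            row += [repr(float(v)) for v in ds.values[i]]
            fh.write(delim.join(row) + "\n")


def load_predictions(path: str, ds: TimeSeriesDataset) -> PredictionSet:
    """Load precomputed black-box predictions aligned to ``ds``.

    Accepts a two-column ``id,label`` CSV (any row order; realigned by id) or
    a single-column label list (row order must match the dataset).
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path} is empty")
    rows = [ln.split(",") for ln in lines]
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise ParseError(f"{path}: inconsistent column counts")

    # optional header
    first = [tok.strip().lower() for tok in rows[0]]
    if first == ["id", "label"] or first == ["label"]:
        rows = rows[1:]
        if not rows:
            raise EmptyInputError(f"{path} has a header but no predictions")

    if ncols == 1:
        labels = [_coerce_label(r[0]) for r in rows]
        if len(labels) != ds.n_instances:
            raise AlignmentError(
                f"{len(labels)} predictions for {ds.n_instances} instances"
            )
        return PredictionSet(labels=labels, source="file")
    if ncols == 2:
        by_id = {}
        for r in rows:
            key = r[0].strip()
            if key in by_id:
                raise AlignmentError(f"duplicate prediction id {key!r}")
            by_id[key] = _coerce_label(r[1])
        unknown = set(by_id) - set(ds.instance_ids)
        if unknown:
            raise AlignmentError(f"prediction ids not in dataset: {sorted(unknown)[:5]}")
        missing = [i for i in ds.instance_ids if i not in by_id]
        if missing:
            raise AlignmentError(f"no prediction for instances: {missing[:5]}")
        return PredictionSet(labels=[by_id[i] for i in ds.instance_ids], source="file")
    raise ParseError(f"{path}: expected 1 or 2 columns, got {ncols}")
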