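"""Domain containers and file I/O for feature blocks, labels, and masks.

A *feature block* is one named samples × features matrix, typically the
activations of a fully-connected or average-pooling layer of a pretrained
CNN applied to a set of lesion images.  Blocks travel as CSV (UTF-8,
mandatory header row, "." decimal separator) or as Parquet when a columnar
binary format is preferred.  Selection masks are stored as a single line of
0/1 characters with a JSON sidecar carrying the selected count and,
optionally, the column-origin map of the fused matrix they index.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureBlock",
    "LabelVector",
    "Dataset",
    "SelectionMask",
    "read_feature_block",
    "write_feature_block",
    "read_labels",
    "write_labels",
    "read_mask",
    "write_mask",
    "assemble_dataset",
]


class FeatureParseError(ValueError):
    """A feature or label file could not be parsed into a valid container."""


@dataclass(frozen=True)
class FeatureBlock:
    """One named matrix of per-sample feature values.

    Parameters
    ----------
    name
        Short identifier, unique within a dataset (e.g. ``"FV2"``).
    values
        Real matrix of shape ``(n_samples, n_features)``; all entries must
        be finite.  Stored as ``float64``.
    source_tag
        Free text naming the emulated extractor/layer
        (e.g. ``"InceptionV3/avg_pool"``).
    column_names
        Optional per-column names; defaults to ``name_0 .. name_{p-1}``.
    """

    name: str
    values: np.ndarray
    source_tag: str = ""
    column_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"block {self.name!r}: values must be 2-D, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"block {self.name!r}: empty matrix of shape {arr.shape}")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(f"block {self.name!r}: non-finite value at row {i}, column {j}")
        if not self.name:
            raise ValueError("block name must be non-empty")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        if not self.column_names:
            object.__setattr__(
                self, "column_names", tuple(f"{self.name}_{j}" for j in range(arr.shape[1]))
            )
        elif len(self.column_names) != arr.shape[1]:
            raise ValueError(
                f"block {self.name!r}: {len(self.column_names)} column names for "
                f"{arr.shape[1]} columns"
            )

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class LabelVector:
    """Per-sample class labels with an explicit positive class.

    ``classes`` keeps first-appearance order; ``positive_class`` marks which
    class plays "malignant" in confusion accounting and defaults to the
    second class when two or more are present.
    """

    labels: tuple[str, ...]
    classes: tuple[str, ...] = ()
    positive_class: str = ""

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        if not labels:
            raise ValueError("label vector must be non-empty")
        object.__setattr__(self, "labels", labels)
        if not self.classes:
            seen: dict[str, None] = {}
            for lab in labels:
                seen.setdefault(lab, None)
            object.__setattr__(self, "classes", tuple(seen))
        unknown = set(labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in declared classes {self.classes}")
        if not self.positive_class:
            pos = self.classes[1] if len(self.classes) >= 2 else self.classes[0]
            object.__setattr__(self, "positive_class", pos)
        if self.positive_class not in self.classes:
            raise ValueError(f"positive_class {self.positive_class!r} not in {self.classes}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


@dataclass(frozen=True)
class Dataset:
    """Ordered feature blocks sharing ``n_samples`` plus aligned labels."""

    blocks: tuple[FeatureBlock, ...]
    labels: LabelVector

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("dataset needs at least one feature block")
        names = [b.name for b in self.blocks]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate block names: {sorted(dupes)}")
        n = self.blocks[0].n_samples
        for b in self.blocks:
            if b.n_samples != n:
                raise ValueError(
                    f"block {b.name!r} has {b.n_samples} samples, expected {n}"
                )
        if len(self.labels) != n:
            raise ValueError(
                f"label count {len(self.labels)} does not match sample count {n}"
            )
        present = {lab for lab in self.labels.labels}
        if len(present) < 2:
            raise ValueError("dataset must contain at least two classes")

    @property
    def n_samples(self) -> int:
        return self.blocks[0].n_samples

    def block(self, name: str) -> FeatureBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no block named {name!r}")


@dataclass(frozen=True)
class SelectionMask:
    """Binary inclusion mask over the columns of a fused feature matrix."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 1:
            raise ValueError("mask bits must be 1-D")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("mask bits must be 0/1")
        bits = bits.astype(np.int8).copy()
        if bits.sum() < 1:
            raise ValueError("selection mask must keep at least one column")
        bits.setflags(write=False)
        object.__setattr__(self, "bits", bits)

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    @property
    def n_columns(self) -> int:
        return int(self.bits.size)

    @property
    def support(self) -> np.ndarray:
        """Indices of the selected columns, ascending."""
        return np.flatnonzero(self.bits)


# ---------------------------------------------------------------------------
# file I/O


def _check_numeric_frame(df: pd.DataFrame, path: os.PathLike | str) -> np.ndarray:
    arr = df.to_numpy()
    if arr.dtype == object:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise FeatureParseError(
                    f"{path}: non-numeric cell at row {i}, column {col!r}"
                )
        arr = df.apply(pd.to_numeric).to_numpy(dtype=np.float64)
    arr = arr.astype(np.float64, copy=False)
    if not np.isfinite(arr).all():
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise FeatureParseError(
            f"{path}: missing or non-finite value at row {i}, column {df.columns[j]!r}"
        )
    return arr


def read_feature_block(
    path: os.PathLike | str,
    format: str = "delimited",
    name: str | None = None,
    source_tag: str = "",
) -> FeatureBlock:
    """Read a feature block from CSV (``delimited``) or Parquet (``columnar-binary``).

    Delimited files must carry a single header row of column names.  Any
    non-numeric, missing, or non-finite cell raises :class:`FeatureParseError`
    naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        try:
            # round_trip parsing keeps read∘write exact at float64 precision
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.ParserError as exc:  # ragged rows
            raise FeatureParseError(f"{path}: {exc}") from exc
    elif format == "columnar-binary":
        df = pd.read_parquet(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    values = _check_numeric_frame(df, path)
    return FeatureBlock(
        name=name or path.stem,
        values=values,
        source_tag=source_tag,
        column_names=tuple(str(c) for c in df.columns),
    )


def write_feature_block(
    block: FeatureBlock, path: os.PathLike | str, format: str = "delimited"
) -> None:
    """Write a block so that reading it back reproduces the values exactly.

    CSV uses ``repr``-shortest float formatting, which round-trips float64.
    """
    path = Path(path)
    df = pd.DataFrame(np.asarray(block.values), columns=list(block.column_names))
    if format == "delimited":
        df.to_csv(path, index=False)
    elif format == "columnar-binary":
        df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: os.PathLike | str, positive_class: str = "") -> LabelVector:
    """Read labels from one-label-per-line text or a two-column sample,label CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise FeatureParseError(f"{path}: no labels found")
    if "," in lines[0]:
        df = pd.read_csv(path)
        if df.shape[1] != 2:
            raise FeatureParseError(f"{path}: expected two columns (sample, label)")
        labels = tuple(str(x) for x in df.iloc[:, 1])
    else:
        labels = tuple(lines)
    return LabelVector(labels=labels, positive_class=positive_class)


def write_labels(labels: LabelVector, path: os.PathLike | str) -> None:
    Path(path).write_text("\n".join(labels.labels) + "\n", encoding="utf-8")


def write_mask(
    mask: SelectionMask,
    path: os.PathLike | str,
    column_origin: Sequence[tuple[str, int]] | None = None,
) -> None:
    """Serialize a mask as a 0/1 line plus a ``<path>.json`` sidecar."""
    path = Path(path)
    path.write_text("".join(str(int(b)) for b in mask.bits) + "\n", encoding="utf-8")
    sidecar = {
        "selected_count": mask.selected_count,
        "n_columns": mask.n_columns,
        "column_origin": (
            [[name, int(j)] for name, j in column_origin] if column_origin else None
        ),
    }
    Path(str(path) + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )


def read_mask(path: os.PathLike | str) -> SelectionMask:
    line = Path(path).read_text(encoding="utf-8").strip()
    if not line or set(line) - {"0", "1"}:
        raise FeatureParseError(f"{path}: mask line must contain only 0/1 characters")
    return SelectionMask(bits=np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))


def assemble_dataset(
    blocks: Sequence[FeatureBlock], labels: LabelVector
) -> Dataset:
    """Build an invariant-checked :class:`Dataset`; any mismatch raises."""
    return Dataset(blocks=tuple(blocks), labels=labels)
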