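"""Readers and writers for the interchange formats used by the pipeline.

The expression matrix travels as GCT (version line ``#1.2``, a dimensions
line, then a header with ``Name``/``Description`` columns), phenotype labels
as CLS, pathway catalogs as GMT, and everything else (annotation layers,
assay plates, results) as headered TSV.  All identifiers are opaque,
case-sensitive strings; no normalization is applied on read or write.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ExpressionStudy",
    "read_gct",
    "write_gct",
    "read_cls",
    "write_cls",
    "read_gmt",
    "write_gmt",
    "read_tsv_table",
    "write_tsv_table",
    "read_study",
    "file_checksum",
]


class ParseError(ValueError):
    """A malformed input file; carries the path and 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")


@dataclass
class ExpressionStudy:
    """A two-class expression study: log2 intensities plus phenotype labels.

    ``values`` is probesets x samples; ``labels`` assigns each sample to one
    of exactly two classes.  The first class in ``classes`` is the treatment
    (positive) class: ranking scores are oriented so that positive means
    "up in treatment".
    """

    values: pd.DataFrame
    labels: pd.Series
    classes: tuple[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"samples without a class label: {missing}")
        uniq = list(dict.fromkeys(self.labels))
        if len(uniq) != 2:
            raise ValueError(f"need exactly two classes, got {uniq}")
        if self.classes is None:
            self.classes = (uniq[0], uniq[1])
        elif set(self.classes) != set(uniq):
            raise ValueError(f"declared classes {self.classes} != labels {uniq}")
        counts = self.labels.value_counts()
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")
        if self.values.index.has_duplicates:
            dups = list(self.values.index[self.values.index.duplicated()][:5])
            raise ValueError(f"duplicate probeset ids: {dups}")

    @property
    def n_samples_per_class(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def class_columns(self, cls: str) -> list[str]:
        return list(self.labels.index[self.labels == cls])

    def with_swapped_labels(self) -> "ExpressionStudy":
        """Same data with the two class roles exchanged (treatment <-> control)."""
        return ExpressionStudy(
            values=self.values,
            labels=self.labels,
            classes=(self.classes[1], self.classes[0]),
        )


# ---------------------------------------------------------------------------
# GCT

def read_gct(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a GCT file; returns (values frame, per-row description series)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#1."):
        raise ParseError(path, 1, "missing GCT version line (expected '#1.2')")
    try:
        nrow, ncol = (int(tok) for tok in lines[1].split("\t")[:2])
    except (IndexError, ValueError):
        raise ParseError(path, 2, "malformed dimensions line") from None
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name" or header[1] != "Description":
        raise ParseError(path, 3, "header must start with 'Name\\tDescription'")
    samples = header[2:]
    if len(samples) != ncol:
        raise ParseError(path, 3, f"dimensions line declares {ncol} samples, header has {len(samples)}")
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != nrow:
        raise ParseError(path, 2, f"dimensions line declares {nrow} rows, file has {len(body)}")
    names, descs, rows = [], [], []
    for i, ln in enumerate(body, start=4):
        parts = ln.split("\t")
        if len(parts) != ncol + 2:
            raise ParseError(path, i, f"expected {ncol + 2} fields, got {len(parts)}")
        names.append(parts[0])
        descs.append(parts[1])
        try:
            rows.append([float(x) for x in parts[2:]])
        except ValueError as exc:
            raise ParseError(path, i, f"non-numeric value: {exc}") from None
    values = pd.DataFrame(np.asarray(rows, dtype=float), index=pd.Index(names, name="Name"), columns=samples)
    return values, pd.Series(descs, index=values.index, name="Description")


def write_gct(values: pd.DataFrame, path, descriptions: pd.Series | None = None) -> None:
    path = Path(path)
    if descriptions is None:
        descriptions = pd.Series("na", index=values.index)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, values.columns)) + "\n")
        for name, row in values.iterrows():
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{name}\t{descriptions.loc[name]}\t{vals}\n")


# ---------------------------------------------------------------------------
# CLS

def read_cls(path) -> tuple[list[str], tuple[str, str]]:
    """Read a two-class categorical CLS file; returns (per-sample labels, class names).

    The first name on the ``#`` line is taken as the treatment class.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh.read().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ParseError(path, max(1, len(lines)), "CLS needs 3 lines (counts, names, labels)")
    head = lines[0].split()
    if len(head) != 3:
        raise ParseError(path, 1, "first line must be '<n_samples> <n_classes> 1'")
    n_samples, n_classes = int(head[0]), int(head[1])
    if n_classes != 2:
        raise ParseError(path, 1, f"only two-class studies supported, got {n_classes}")
    if not lines[1].startswith("#"):
        raise ParseError(path, 2, "second line must start with '#' and list class names")
    names = lines[1][1:].split()
    if len(names) != 2:
        raise ParseError(path, 2, f"expected 2 class names, got {len(names)}")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise ParseError(path, 3, f"declared {n_samples} samples but found {len(tokens)} labels")
    # Tokens may be the class names themselves or 0/1 indices in name order.
    labels = []
    for j, tok in enumerate(tokens):
        if tok in names:
            labels.append(tok)
        elif tok in ("0", "1"):
            labels.append(names[int(tok)])
        else:
            raise ParseError(path, 3, f"label token {j + 1} ({tok!r}) matches no declared class")
    seen = set(labels)
    if len(seen) != 2:
        raise ParseError(path, 3, f"labels use {len(seen)} of the 2 declared classes")
    return labels, (names[0], names[1])


def write_cls(labels: Sequence[str], classes: tuple[str, str], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write(f"# {classes[0]} {classes[1]}\n")
        fh.write(" ".join(labels) + "\n")


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Read a GMT catalog; returns (name -> member list, name -> description)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descs: dict[str, str] = {}
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ParseError(path, i, "GMT line needs name, description and >= 1 member")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise ParseError(path, i, f"set {name!r} has no members")
            if name in sets:
                raise ParseError(path, i, f"duplicate set name {name!r}")
            sets[name] = members
            descs[name] = desc
    return sets, descs


def write_gmt(sets: Mapping[str, Sequence[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Generic TSV tables

def read_tsv_table(path, required: Sequence[str] = ()) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing required columns: {missing}")
    return df


def write_tsv_table(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), sep="\t", index=False)


def read_study(gct_path, cls_path) -> ExpressionStudy:
    """Assemble an :class:`ExpressionStudy` from a GCT matrix and CLS labels."""
    values, _ = read_gct(gct_path)
    labels, classes = read_cls(cls_path)
    if len(labels) != values.shape[1]:
        raise ParseError(cls_path, 1, f"CLS lists {len(labels)} samples, GCT has {values.shape[1]}")
    return ExpressionStudy(
        values=values,
        labels=pd.Series(labels, index=values.columns, name="class"),
        classes=classes,
    )


def file_checksum(path) -> str:
    """MD5 of a file's bytes, for run-log provenance."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
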