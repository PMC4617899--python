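"""Readers and writers for the GSEA-ecosystem file formats.

Supported formats: GCT 1.2 and plain tab-delimited expression matrices,
categorical CLS phenotype labels, GMT (one set per row) and GMX (one set per
column) gene set collections, and TSV result tables.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ExpressionDataset,
    FormatError,
    GeneSet,
    GeneSetCollection,
    ValidationError,
)

__all__ = [
    "read_expression",
    "read_cls",
    "read_gene_sets",
    "write_expression_gct",
    "write_cls",
    "write_gene_sets_gmt",
    "write_table",
]


def _lines(path) -> list[str]:
    text = Path(path).read_text()
    return [ln.rstrip("\r\n") for ln in text.splitlines()]


def _parse_cell(token: str, row: int, col: int, path) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}: non-numeric value {token!r} at data row {row + 1}, column {col + 1}"
        ) from None


def read_expression(path, format: str | None = None, log2_input: bool = False,
                    class_of: dict[str, str] | None = None) -> ExpressionDataset:
    """Load an expression matrix from a GCT 1.2 or plain tab-delimited file.

    Parameters
    ----------
    format : ``"gct"`` or ``"txt"``; inferred from the suffix when omitted.
    log2_input : when True the file stores log2 intensities and values are
        exponentiated base 2 on load, so downstream ratios are linear-scale
        fold changes.
    class_of : optional sample -> class map (usually from :func:`read_cls`);
        when omitted every sample is placed in a single class ``"all"`` and
        the map must be attached before any contrast is computed.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "txt"
    if format not in ("gct", "txt"):
        raise ValidationError(f"unknown expression format: {format!r}")

    lines = [ln for ln in _lines(path)]
    if format == "gct":
        if not lines or lines[0].strip() != "#1.2":
            raise FormatError(f"{path}: missing GCT '#1.2' version header")
        try:
            n_genes, n_samples = (int(t) for t in lines[1].split())
        except (IndexError, ValueError):
            raise FormatError(f"{path}: malformed GCT dimension line") from None
        header = lines[2].split("\t")
        sample_names = header[2:]
        if len(sample_names) != n_samples:
            raise FormatError(
                f"{path}: dimension line declares {n_samples} samples "
                f"but header has {len(sample_names)}"
            )
        rows = [ln.split("\t") for ln in lines[3:] if ln.strip()]
        if len(rows) != n_genes:
            raise FormatError(
                f"{path}: dimension line declares {n_genes} rows but file has {len(rows)}"
            )
        ids, descs, data = [], [], []
        for r, row in enumerate(rows):
            if len(row) != n_samples + 2:
                raise FormatError(f"{path}: row {r + 1} has {len(row)} fields, expected {n_samples + 2}")
            ids.append(row[0])
            descs.append(row[1])
            data.append([_parse_cell(t, r, c, path) for c, t in enumerate(row[2:])])
        descriptions: list[str] | None = descs
    else:
        if not lines:
            raise FormatError(f"{path}: empty file")
        header = lines[0].split("\t")
        has_desc = len(header) > 1 and header[1].strip().lower() in ("description", "desc")
        first_data = 2 if has_desc else 1
        sample_names = header[first_data:]
        if not sample_names:
            raise FormatError(f"{path}: header declares no sample columns")
        ids, descs, data = [], [], []
        for r, ln in enumerate(lines[1:]):
            if not ln.strip():
                continue
            row = ln.split("\t")
            if len(row) != len(header):
                raise FormatError(f"{path}: row {r + 1} has {len(row)} fields, expected {len(header)}")
            ids.append(row[0])
            descs.append(row[1] if has_desc else "")
            data.append([_parse_cell(t, r, c, path) for c, t in enumerate(row[first_data:])])
        descriptions = descs if has_desc else None

    seen: set[str] = set()
    for g in ids:
        if g in seen:
            raise ValidationError(f"{path}: duplicate gene identifier {g!r}")
        seen.add(g)

    values = np.asarray(data, dtype=float)
    if log2_input:
        values = np.exp2(values)
    if class_of is None:
        class_of = {s: "all" for s in sample_names}
    return ExpressionDataset(
        identifiers=ids,
        values=values,
        sample_names=list(sample_names),
        class_of=dict(class_of),
        descriptions=descriptions,
    )


def read_cls(path) -> tuple[dict[str, str], list[str]]:
    """Parse a categorical CLS file.

    Returns ``(class_of_position, class_order)`` where ``class_of_position``
    maps the 0-based sample position (as a string index key ``"0"``, ``"1"``,
    ...) only when sample names are unknown; callers normally zip the labels
    with the sample names of the matching expression file via
    :func:`attach_classes`.

    The third line accepts either the declared class names or 0-based indices
    into the declared name list (both dialects are common in the wild).
    """
    lines = [ln for ln in _lines(path) if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS needs 3 non-empty lines")
    head = lines[0].split()
    if len(head) != 3:
        raise FormatError(f"{path}: CLS first line must be 'N k 1'")
    n, k, one = (int(t) for t in head)
    if one != 1:
        raise FormatError(f"{path}: third field of the CLS header must be 1 (categorical)")
    name_line = lines[1].split()
    if not name_line or name_line[0] != "#":
        raise FormatError(f"{path}: CLS second line must start with '#'")
    names = name_line[1:]
    if len(names) != k:
        raise FormatError(f"{path}: header declares {k} classes but {len(names)} are named")
    tokens = lines[2].split()
    if len(tokens) != n:
        raise FormatError(f"{path}: header declares {n} samples but {len(tokens)} labels found")
    if all(t.isdigit() for t in tokens) and set(names) != set(tokens):
        labels = []
        for t in tokens:
            i = int(t)
            if i >= k:
                raise FormatError(f"{path}: numeric label {i} >= declared class count {k}")
            labels.append(names[i])
    else:
        bad = [t for t in tokens if t not in names]
        if bad:
            raise FormatError(f"{path}: labels {sorted(set(bad))} not among declared class names")
        labels = tokens
    if len(set(labels)) != k:
        raise FormatError(
            f"{path}: {k} classes declared but {len(set(labels))} distinct labels used"
        )
    return {str(i): lab for i, lab in enumerate(labels)}, names


def attach_classes(dataset: ExpressionDataset, cls: tuple[dict[str, str], list[str]]) -> ExpressionDataset:
    """Return a copy of ``dataset`` labeled by a parsed CLS file (positional)."""
    label_of_pos, order = cls
    if len(label_of_pos) != dataset.n_samples:
        raise ValidationError(
            f"CLS labels {len(label_of_pos)} samples but dataset has {dataset.n_samples}"
        )
    class_of = {s: label_of_pos[str(i)] for i, s in enumerate(dataset.sample_names)}
    return ExpressionDataset(
        identifiers=list(dataset.identifiers),
        values=dataset.values.copy(),
        sample_names=list(dataset.sample_names),
        class_of=class_of,
        descriptions=None if dataset.descriptions is None else list(dataset.descriptions),
        class_order=[c for c in order if c in set(class_of.values())],
    )


def read_gene_sets(path, format: str | None = None) -> GeneSetCollection:
    """Load a GMT (row-wise) or GMX (column-wise) gene set collection."""
    path = Path(path)
    if format is None:
        format = path.suffix.lower().lstrip(".")
    if format not in ("gmt", "gmx"):
        raise ValidationError(f"unknown gene set format: {format!r}")
    lines = [ln for ln in _lines(path) if ln.strip()]
    sets: list[GeneSet] = []
    if format == "gmt":
        for i, ln in enumerate(lines):
            row = ln.split("\t")
            if len(row) < 3:
                raise FormatError(f"{path}: GMT line {i + 1} has fewer than 3 columns")
            members = [t for t in row[2:] if t.strip()]
            if not members:
                raise FormatError(f"{path}: GMT line {i + 1} declares no members")
            sets.append(GeneSet(name=row[0], description=row[1], members=frozenset(members)))
    else:
        if len(lines) < 3:
            raise FormatError(f"{path}: GMX needs a name row, a description row and members")
        grid = [ln.split("\t") for ln in lines]
        names = grid[0]
        descs = grid[1] + [""] * (len(names) - len(grid[1]))
        for j, name in enumerate(names):
            members = [row[j] for row in grid[2:] if j < len(row) and row[j].strip()]
            if not members:
                raise FormatError(f"{path}: GMX column {j + 1} ({name!r}) declares no members")
            sets.append(GeneSet(name=name, description=descs[j], members=frozenset(members)))
    try:
        return GeneSetCollection(sets)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from None


def write_gene_sets_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection as GMT; members are emitted in sorted order."""
    if len(collection) == 0:
        raise ValidationError("refusing to write an empty gene set collection")
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def write_expression_gct(dataset: ExpressionDataset, path) -> None:
    """Write a dataset as GCT 1.2 (linear-scale values, full precision)."""
    descs = dataset.descriptions or ["na"] * dataset.n_genes
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{dataset.n_genes}\t{dataset.n_samples}\n")
        fh.write("\t".join(["NAME", "Description", *dataset.sample_names]) + "\n")
        for g, d, row in zip(dataset.identifiers, descs, dataset.values):
            fh.write("\t".join([g, d, *(repr(float(v)) for v in row)]) + "\n")


def write_cls(dataset: ExpressionDataset, path) -> None:
    """Write the dataset's class labels as a categorical CLS file."""
    labels = [dataset.class_of[s] for s in dataset.sample_names]
    with open(path, "w") as fh:
        fh.write(f"{dataset.n_samples} {len(dataset.classes)} 1\n")
        fh.write("# " + " ".join(dataset.classes) + "\n")
        fh.write(" ".join(labels) + "\n")


def write_table(rows: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a result table as TSV (header always written; empty tables warn)."""
    if len(rows) == 0:
        warnings.warn(f"writing empty result table to {path}", stacklevel=2)
    rows.to_csv(path, sep="\t", index=False, float_format=float_format)
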