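"""Domain types shared across the package.

The central container is :class:`ExpressionDataset`: a genes x samples matrix
of normalized intensities on *linear* scale together with a sample -> phenotype
class map.  Gene sets are plain named identifier collections compatible with
the GSEA ecosystem (GMT/GMX files).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


class BubbleGumError(Exception):
    """Base class for all package errors."""


class FormatError(BubbleGumError):
    """A file does not conform to its declared format."""


class ValidationError(BubbleGumError):
    """Input values violate a documented precondition."""


class ReplicateCountError(ValidationError):
    """A statistical procedure was requested with too few replicates."""


class GeneSetSizeSkip(BubbleGumError):
    """Signal (not a failure): a gene set fell outside the size filter.

    Raised by the enrichment-score path so drivers can record the set as
    skipped instead of aborting the whole analysis.
    """

    def __init__(self, name: str, size: int, lo: int, hi: int):
        super().__init__(f"gene set {name!r}: {size} members in dataset, outside [{lo}, {hi}]")
        self.name, self.size, self.lo, self.hi = name, size, lo, hi


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            raise ValidationError(f"duplicate {what}: {it!r}")
        seen.add(it)


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with phenotype class labels.

    Parameters
    ----------
    identifiers : ordered unique gene identifiers (one per row).
    values : 2-D float array, shape ``(n_genes, n_samples)``, finite.
        Linear-scale intensities; strict positivity is only enforced when a
        ratio-based statistic is invoked.
    sample_names : ordered unique sample names (one per column).
    class_of : mapping sample name -> phenotype class label.
    descriptions : optional per-gene free text.
    class_order : optional explicit ordering of the class labels (defaults to
        first appearance in sample order).
    """

    identifiers: list[str]
    values: np.ndarray
    sample_names: list[str]
    class_of: dict[str, str]
    descriptions: list[str] | None = None
    class_order: list[str] | None = None

    def __post_init__(self) -> None:
        self.identifiers = [str(g) for g in self.identifiers]
        self.sample_names = [str(s) for s in self.sample_names]
        if not self.identifiers:
            raise ValidationError("dataset has no gene identifiers")
        if not self.sample_names:
            raise ValidationError("dataset has no samples")
        _check_unique(self.identifiers, "gene identifier")
        _check_unique(self.sample_names, "sample name")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.identifiers), len(self.sample_names)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.identifiers)} genes x {len(self.sample_names)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        missing = [s for s in self.sample_names if s not in self.class_of]
        if missing:
            raise ValidationError(f"samples without a class label: {missing}")
        if self.class_order is None:
            order: list[str] = []
            for s in self.sample_names:
                c = self.class_of[s]
                if c not in order:
                    order.append(c)
            self.class_order = order
        else:
            labels = {self.class_of[s] for s in self.sample_names}
            if set(self.class_order) != labels:
                raise ValidationError("class_order does not match the labels in class_of")
        if self.descriptions is not None and len(self.descriptions) != len(self.identifiers):
            raise ValidationError("descriptions length does not match identifiers")

    # -- convenience ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.identifiers)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    @property
    def classes(self) -> list[str]:
        return list(self.class_order or [])

    def samples_of(self, label: str) -> np.ndarray:
        """Column indices of the samples belonging to ``label``."""
        if label not in set(self.class_order or []):
            raise ValidationError(f"unknown phenotype class: {label!r}")
        return np.array(
            [i for i, s in enumerate(self.sample_names) if self.class_of[s] == label],
            dtype=int,
        )

    def replicate_count(self, label: str) -> int:
        return len(self.samples_of(label))

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.identifiers)}


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene identifiers."""

    name: str
    description: str = ""
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        object.__setattr__(self, "members", frozenset(str(m) for m in self.members if m))
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Ordered list of gene sets with unique names."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene set name")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def match_members(
    members: Iterable[str],
    identifiers: Sequence[str],
    case_sensitive: bool = False,
) -> np.ndarray:
    """Row indices of ``identifiers`` matching ``members``.

    Matching is case-insensitive exact string comparison by default (gene
    symbol conventions differ in capitalization across species); genes in the
    set but absent from the identifiers are silently dropped.  Returned
    indices are sorted ascending.
    """
    if case_sensitive:
        index = {g: i for i, g in enumerate(identifiers)}
        hits = {index[m] for m in members if m in index}
    else:
        index = {}
        for i, g in enumerate(identifiers):
            index.setdefault(g.upper(), i)
        hits = {index[m.upper()] for m in members if m.upper() in index}
    return np.array(sorted(hits), dtype=int)
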