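"""Synthetic expression datasets with planted class-specific signatures.

The generator emulates RMA-normalized microarray intensities: log2 values are
``baseline + effect * [gene planted for the sample's class] + N(0, noise_sd)``
and the dataset stores ``2**log2`` (linear scale, strictly positive).  The
default fixture mirrors a small multi-phenotype immunology study: 7 classes
in triplicate, 2,000 genes, planted blocks of 50 genes at a 2.0 log2
(four-fold) effect for six of the classes, the seventh left without a block
as a negative control.

Alongside each dataset the generator returns the ground truth (which genes
were planted for which class) and can build a matching gene set collection:
one "fingerprint" set per planted block plus randomly drawn padding sets,
the planted names carrying a filterable infix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ExpressionDataset, GeneSet, GeneSetCollection, ValidationError

__all__ = ["SimulationSpec", "simulate_dataset", "simulate_gene_sets",
           "PLANTED_INFIX", "default_spec", "null_spec"]

PLANTED_INFIX = "humS"  # tag distinguishing fingerprint sets from padding


@dataclass
class SimulationSpec:
    """Parameters of the planted-signature generator.

    ``planted_blocks`` maps class label -> (gene count, log2 effect size);
    blocks are disjoint and assigned in class order from the start of the
    gene list.  ``noise_sd`` is the log2-scale standard deviation.
    """

    n_genes: int = 2000
    classes: dict[str, int] = field(
        default_factory=lambda: {f"P{i + 1}": 3 for i in range(7)})
    planted_blocks: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {f"P{i + 1}": (50, 2.0) for i in range(6)})
    noise_sd: float = 0.5
    baseline_log2: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if any(r < 2 for r in self.classes.values()):
            raise ValidationError("every class needs at least 2 replicates")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        unknown = set(self.planted_blocks) - set(self.classes)
        if unknown:
            raise ValidationError(f"planted blocks for unknown classes: {sorted(unknown)}")
        total = sum(n for n, _ in self.planted_blocks.values())
        if total > self.n_genes:
            raise ValidationError("planted blocks exceed the gene count")
        if any(e <= 0 for _, e in self.planted_blocks.values()):
            raise ValidationError("planted effect sizes must be positive")


def default_spec(seed: int = 0) -> SimulationSpec:
    """The standard planted fixture (see module docstring)."""
    return SimulationSpec(seed=seed)


def null_spec(n_genes: int = 2000, n_classes: int = 6, replicates: int = 3,
              seed: int = 0) -> SimulationSpec:
    """A global-null fixture: exchangeable classes, nothing planted."""
    return SimulationSpec(
        n_genes=n_genes,
        classes={f"N{i + 1}": replicates for i in range(n_classes)},
        planted_blocks={},
        seed=seed,
    )


def simulate_dataset(spec: SimulationSpec) -> tuple[ExpressionDataset, dict[str, list[str]]]:
    """Generate a dataset and its ground-truth map class -> planted genes."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    sample_names, class_of = [], {}
    for c, r in spec.classes.items():
        for j in range(r):
            s = f"{c}_rep{j + 1}"
            sample_names.append(s)
            class_of[s] = c

    log2 = spec.baseline_log2 + rng.normal(0.0, spec.noise_sd,
                                           size=(spec.n_genes, len(sample_names)))
    truth: dict[str, list[str]] = {}
    start = 0
    col_of_class = {c: [i for i, s in enumerate(sample_names) if class_of[s] == c]
                    for c in spec.classes}
    for c, (n_block, effect) in spec.planted_blocks.items():
        rows = slice(start, start + n_block)
        log2[rows, :][:, col_of_class[c]] += effect
        truth[c] = genes[rows]
        start += n_block

    dataset = ExpressionDataset(
        identifiers=genes,
        values=np.exp2(log2),
        sample_names=sample_names,
        class_of=class_of,
        class_order=list(spec.classes),
    )
    return dataset, truth


def simulate_gene_sets(ground_truth: dict[str, list[str]], n_random_sets: int,
                       size_range: tuple[int, int], seed: int,
                       gene_universe: list[str] | None = None) -> GeneSetCollection:
    """Fingerprint sets (one per planted block) plus random padding sets.

    Random sets are uniform draws without replacement from ``gene_universe``
    (defaults to the union of planted genes when not given, which is rarely
    what you want — pass the dataset's identifiers).  Padding mirrors the
    practice of mixing in unrelated gene sets so the multiple-testing
    correction has a mostly-null family to work on.
    """
    rng = np.random.default_rng(seed)
    if gene_universe is None:
        gene_universe = sorted({g for gs in ground_truth.values() for g in gs})
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(gene_universe):
        raise ValidationError(
            f"size range {size_range} invalid for a universe of {len(gene_universe)} genes")
    sets = [
        GeneSet(name=f"{c}_fingerprint_{PLANTED_INFIX}",
                description=f"planted signature genes of class {c}",
                members=frozenset(genes))
        for c, genes in ground_truth.items()
    ]
    universe = np.asarray(gene_universe)
    for i in range(n_random_sets):
        k = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=k, replace=False)
        sets.append(GeneSet(name=f"RANDOM_{i + 1:03d}",
                            description="randomly drawn padding set",
                            members=frozenset(members.tolist())))
    return GeneSetCollection(sets)
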