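"""Exhaustive pairwise GSEA with map-wide multiple-testing correction.

For every unordered pair of phenotype classes and every gene set surviving
the size filter, the driver computes ES, NES and a permutation null (gene-set
or sample permutations).  The normalized null scores are pooled across *all*
cells of the map, per sign, and each cell's p-value is the never-zero
``(b+1)/(m+1)`` tail count against that pool.  FDR is then controlled over
the whole map family (gene sets x unordered pairs) with the
Benjamini-Yekutieli procedure, which is valid under the arbitrary dependence
the shared samples and overlapping sets induce.

Directed views (both orientations of every pair, as displayed) are produced
by sign-flipping the computed cell; the mirrored cell carries identical p
and FDR.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    ExpressionDataset,
    GeneSetCollection,
    GeneSetSizeSkip,
    ValidationError,
)
from .genesign import adjust_pvalues
from . import gsea

__all__ = [
    "enumerate_comparisons",
    "run_bubblemap",
    "map_pvalues",
    "global_fdr",
    "filter_grid",
    "BubbleMapResult",
]


def enumerate_comparisons(classes: list[str]) -> list[tuple[str, str]]:
    """All ordered pairs of distinct classes, n*(n-1), in input order."""
    if len(classes) < 2:
        raise ValidationError("need at least 2 phenotype classes to compare")
    if len(set(classes)) != len(classes):
        raise ValidationError("class labels must be unique")
    return [(a, b) for a in classes for b in classes if b != a]


def unordered_pairs(classes: list[str]) -> list[tuple[str, str]]:
    """Each pair once, left = earlier class in input order."""
    if len(classes) < 2:
        raise ValidationError("need at least 2 phenotype classes to compare")
    return [(classes[i], classes[j])
            for i in range(len(classes)) for j in range(i + 1, len(classes))]


@dataclass
class BubbleMapResult:
    """One row of ``cells`` per (gene set, unordered comparison).

    Columns: set, left, right, es, nes, p, fdr, enriched_side, size_used,
    flags.  ``metadata`` records everything needed to replay the run.
    """

    cells: pd.DataFrame
    metadata: dict
    skipped: list[tuple[str, int]] = field(default_factory=list)

    @property
    def set_names(self) -> list[str]:
        return list(dict.fromkeys(self.cells["set"]))

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        return list(dict.fromkeys(zip(self.cells["left"], self.cells["right"])))

    def directed(self) -> pd.DataFrame:
        """Both orientations of every pair; the mirror sign-flips es/nes and
        keeps p/fdr (the statistics are antisymmetric, not re-tested)."""
        fwd = self.cells.copy()
        mir = self.cells.copy()
        mir["left"], mir["right"] = self.cells["right"], self.cells["left"]
        mir["es"], mir["nes"] = -mir["es"], -mir["nes"]
        out = pd.concat([fwd, mir], ignore_index=True)
        return out


def _fingerprint_dataset(dataset: ExpressionDataset) -> str:
    h = hashlib.sha256()
    h.update("\x00".join(dataset.identifiers).encode())
    h.update("\x00".join(dataset.sample_names).encode())
    h.update("\x00".join(dataset.class_of[s] for s in dataset.sample_names).encode())
    h.update(np.ascontiguousarray(dataset.values).tobytes())
    return h.hexdigest()[:16]


def _fingerprint_collection(collection: GeneSetCollection) -> str:
    h = hashlib.sha256()
    for s in collection:
        h.update(("\t".join([s.name, *sorted(s.members)]) + "\n").encode())
    return h.hexdigest()[:16]


def map_pvalues(nes: np.ndarray, null_pool: np.ndarray) -> tuple[np.ndarray, list[list[str]]]:
    """Pooled-null p per cell: for a cell of sign s, ``(b+1)/(m+1)`` where b
    counts pooled same-sign null values at least as extreme and m is the
    same-sign pool size.  NaN cells (undefined NES) and cells facing an empty
    same-sign pool fall back to ``1/(m_other+1)`` with a flag."""
    null_pool = np.asarray(null_pool, dtype=float)
    pos_pool = np.sort(null_pool[null_pool > 0])
    neg_pool = np.sort(np.abs(null_pool[null_pool < 0]))
    if pos_pool.size == 0 and neg_pool.size == 0:
        raise ValidationError("empty null pool")
    p = np.empty(len(nes))
    flags: list[list[str]] = [[] for _ in nes]
    for i, v in enumerate(np.asarray(nes, dtype=float)):
        if np.isnan(v):
            p[i] = 1.0 / (max(pos_pool.size, neg_pool.size) + 1)
            flags[i].append("undefined_nes")
            continue
        pool = pos_pool if v >= 0 else neg_pool
        other = neg_pool if v >= 0 else pos_pool
        if pool.size == 0:
            p[i] = 1.0 / (other.size + 1)
            flags[i].append("empty_same_sign_pool")
            continue
        b = pool.size - np.searchsorted(pool, abs(v), side="left")
        p[i] = (b + 1) / (pool.size + 1)
    return p, flags


def global_fdr(p: np.ndarray) -> np.ndarray:
    """Map-wide Benjamini-Yekutieli adjustment over all unique cells."""
    return adjust_pvalues(np.asarray(p, dtype=float), "BY")


def run_bubblemap(dataset: ExpressionDataset, collection: GeneSetCollection,
                  mode: str = "geneset", n_perm: int = 1000, seed: int = 0,
                  weight: float = 1.0, min_size: int = 15, max_size: int = 500,
                  fdr_display_threshold: float = 0.25,
                  min_replicates_override: bool = False,
                  case_sensitive: bool = False) -> BubbleMapResult:
    """GSEA over all unordered class pairs x all surviving gene sets.

    Gene-set permutation nulls depend only on the ranked list and the set
    size, so cells of one comparison sharing a size share one null draw
    (seeded from the run seed, the pair and the size — deterministic and
    independent of which sets are present).
    """
    classes = dataset.classes
    pairs = unordered_pairs(classes)
    if len(collection) == 0:
        raise ValidationError("empty gene set collection")
    if mode not in ("geneset", "sample"):
        raise ValidationError(f"unknown permutation mode {mode!r}")

    records: list[dict] = []
    null_norm_pool: list[np.ndarray] = []
    skipped: dict[str, int] = {}

    for pi, (left, right) in enumerate(pairs):
        ranked = gsea.rank_genes(dataset, left, right)
        stats: list[tuple[str, gsea.EnrichmentStat]] = []
        for gs in collection:
            try:
                st = gsea.enrichment_score(ranked, gs, weight=weight,
                                           min_size=min_size, max_size=max_size,
                                           case_sensitive=case_sensitive)
            except GeneSetSizeSkip as sk:
                skipped[gs.name] = sk.size
                continue
            stats.append((gs.name, st))
        if not stats:
            continue

        if mode == "geneset":
            nulls_by_size: dict[int, np.ndarray] = {}
            for _, st in stats:
                k = st.set_size_used
                if k not in nulls_by_size:
                    ss = np.random.SeedSequence([int(seed), pi, k])
                    nulls_by_size[k] = gsea.null_enrichment_scores(
                        "geneset", n_perm, ss, ranked=ranked, set_size=k,
                        weight=weight)
            null_of = {name: nulls_by_size[st.set_size_used] for name, st in stats}
        else:
            null_of = {}
            for name, st in stats:
                ss = np.random.SeedSequence([int(seed), pi, hash(name) & 0x7FFFFFFF])
                null_of[name] = gsea.null_enrichment_scores(
                    "sample", n_perm, ss, ranked=ranked, dataset=dataset,
                    geneset=collection[name], weight=weight,
                    min_replicates_override=min_replicates_override,
                    case_sensitive=case_sensitive)

        for name, st in stats:
            nes, null_norm = gsea.normalize_es(st.es, null_of[name])
            null_norm_pool.append(null_norm)
            records.append({
                "set": name, "left": left, "right": right,
                "es": st.es,
                "nes": np.nan if nes is None else nes,
                "p": np.nan, "fdr": np.nan,
                "enriched_side": left if st.es > 0 else right,
                "size_used": st.set_size_used,
                "flags": [] if nes is not None else ["undefined_nes"],
                "p_nominal": gsea.nominal_pvalue(st.es, null_of[name]),
            })

    if not records:
        raise ValidationError("every gene set was size-skipped; nothing to analyse")

    cells = pd.DataFrame(records)
    pool = np.concatenate(null_norm_pool)
    p, pflags = map_pvalues(cells["nes"].to_numpy(), pool)
    cells["p"] = p
    cells["fdr"] = global_fdr(p)
    cells["flags"] = [";".join(sorted(set(a) | set(b)))
                      for a, b in zip(cells["flags"], pflags)]

    metadata = {
        "mode": mode, "n_perm": int(n_perm), "seed": int(seed),
        "weight": float(weight), "min_size": int(min_size), "max_size": int(max_size),
        "fdr_display_threshold": float(fdr_display_threshold),
        "classes": list(classes),
        "n_unique_comparisons": len(pairs),
        "n_directed_comparisons": len(classes) * (len(classes) - 1),
        "family_size": int(len(cells)),
        "null_pool_size": int(pool.size),
        "dataset_fingerprint": _fingerprint_dataset(dataset),
        "collection_fingerprint": _fingerprint_collection(collection),
    }
    return BubbleMapResult(cells=cells, metadata=metadata,
                           skipped=sorted(skipped.items()))


def load_cells(path, metadata: dict | None = None) -> BubbleMapResult:
    """Reload a saved cells TSV (see the CLI) for re-rendering."""
    cells = pd.read_csv(path, sep="\t", dtype={"set": str, "left": str, "right": str})
    cells["flags"] = cells.get("flags", "").fillna("") if "flags" in cells else ""
    meta = dict(metadata or {})
    if "classes" not in meta:
        meta["classes"] = list(dict.fromkeys([*cells["left"], *cells["right"]]))
    return BubbleMapResult(cells=cells, metadata=meta)


def filter_grid(result: BubbleMapResult, name_pattern: str = "",
                comparisons: list[tuple[str, str]] | None = None,
                row_order: list[str] | None = None,
                col_order: list[tuple[str, str]] | None = None) -> BubbleMapResult:
    """Display-level view: subset rows by case-insensitive name infix,
    restrict the comparisons, and/or set the display order of rows and
    columns.  Ordering is a view attribute (recorded in the metadata and
    honored by the renderer); the cells table keeps its computation order and
    statistics are never recomputed — the FDR family was fixed at run time."""
    cells = result.cells
    known = set(zip(cells["left"], cells["right"]))
    for key in (comparisons or []) + (col_order or []):
        if tuple(key) not in known:
            raise ValidationError(f"unknown comparison {key!r}")
    mask = cells["set"].str.contains(name_pattern, case=False, regex=False)
    view = cells[mask]
    if comparisons is not None:
        keep = set(tuple(c) for c in comparisons)
        view = view[[tuple(k) in keep for k in zip(view["left"], view["right"])]]
    if col_order is not None:
        keep = set(tuple(c) for c in col_order)
        view = view[[(l, r) in keep for l, r in zip(view["left"], view["right"])]]
    meta = dict(result.metadata)
    present_sets = set(view["set"])
    meta["view"] = {
        "name_pattern": name_pattern,
        "comparisons": [list(c) for c in (comparisons or [])],
        "row_order": [s for s in row_order if s in present_sets]
                     if row_order is not None else None,
        "col_order": [list(c) for c in col_order] if col_order is not None else None,
    }
    return BubbleMapResult(cells=view.reset_index(drop=True), metadata=meta,
                           skipped=list(result.skipped))
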