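"""The original GSEA statistic for one pair of phenotype classes.

Genes are ranked by the signal-to-noise ratio of *left* versus *right*
(positive metric = higher on the left).  A gene set's enrichment score (ES)
is the signed maximum deviation of a running sum that increments at member
genes by their metric magnitude raised to ``weight`` (normalized so the hit
mass sums to 1) and decrements at non-members by ``1/(N - N_hits)``.  With
``weight=0`` this reduces to the classic Kolmogorov-Smirnov statistic.  The
normalized enrichment score (NES) divides ES by the mean magnitude of
same-sign permutation-null scores, making values comparable across set sizes
and comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ExpressionDataset,
    GeneSet,
    GeneSetSizeSkip,
    ReplicateCountError,
    ValidationError,
    match_members,
)
from .genesign import floored_sd, _smallest_positive

__all__ = [
    "RankedList",
    "EnrichmentStat",
    "rank_genes",
    "enrichment_score",
    "null_enrichment_scores",
    "normalize_es",
    "nominal_pvalue",
]

MIN_SAMPLE_PERM_REPLICATES = 5


@dataclass
class RankedList:
    """All dataset genes ordered by a differential metric, descending."""

    genes: list[str]
    metrics: np.ndarray
    class_left: str
    class_right: str

    def __post_init__(self) -> None:
        self.metrics = np.asarray(self.metrics, dtype=float)
        if len(self.genes) != self.metrics.size:
            raise ValidationError("genes and metrics lengths differ")
        if np.any(np.diff(self.metrics) > 0):
            raise ValidationError("metrics must be nonincreasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentStat:
    """ES/NES and bookkeeping for one gene set on one ranked list."""

    es: float
    hit_positions: np.ndarray
    set_size_used: int
    nes: float | None = None
    p_nominal: float | None = None
    flags: list[str] = field(default_factory=list)


def _snr_metrics(dataset: ExpressionDataset, left_cols: np.ndarray,
                 right_cols: np.ndarray) -> np.ndarray:
    X = dataset.values
    delta = _smallest_positive(X)
    out = []
    for cols in (left_cols, right_cols):
        sub = X[:, cols]
        s, ss = sub.sum(axis=1), (sub**2).sum(axis=1)
        m = s / len(cols)
        out.append((m, floored_sd(s, ss, len(cols), m, delta)))
    (lm, lsd), (rm, rsd) = out
    return (lm - rm) / (lsd + rsd)


def rank_genes(dataset: ExpressionDataset, class_left: str, class_right: str) -> RankedList:
    """Rank every dataset gene by SNR(left vs right), descending; ties keep
    input row order (stable sort)."""
    lcols = dataset.samples_of(class_left)
    rcols = dataset.samples_of(class_right)
    for label, cols in ((class_left, lcols), (class_right, rcols)):
        if len(cols) < 2:
            raise ReplicateCountError(
                f"class {label!r} has {len(cols)} replicate(s); the signal-to-noise "
                "ranking metric needs at least 2"
            )
    metrics = _snr_metrics(dataset, lcols, rcols)
    order = np.argsort(-metrics, kind="stable")
    return RankedList(
        genes=[dataset.identifiers[i] for i in order],
        metrics=metrics[order],
        class_left=class_left,
        class_right=class_right,
    )


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _batch_es(absw: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """ES for many hit-position sets on one ranked list.

    ``absw`` is ``|metric|**weight`` over the ranked list (length N);
    ``positions`` is (P, k), each row the sorted 0-based hit positions.  Only
    the running-sum values adjacent to hits can be extrema (the sum is
    linear between hits), so the scan is O(k) per permutation.
    """
    N = absw.size
    P, k = positions.shape
    if not 0 < k < N:
        raise ValidationError("hit count must be in (0, N)")
    w = absw[positions]
    cumw = np.cumsum(w, axis=1)
    nr = cumw[:, -1:].copy()
    flat = nr[:, 0] == 0  # all hit weights zero: fall back to unweighted steps
    if np.any(flat):
        cumw[flat] = np.arange(1, k + 1)
        nr[flat] = k
    miss_den = N - k
    miss_frac = (positions - np.arange(k)) / miss_den
    after = cumw / nr - miss_frac
    before = (cumw - w) / nr - miss_frac
    if np.any(flat):
        before[flat] = (cumw[flat] - 1) / k - miss_frac[flat]
    # earliest position attaining the extremum (ties within rounding noise)
    rows = np.arange(P)
    i_pos = np.argmax(after >= after.max(axis=1, keepdims=True) - 1e-9, axis=1)
    i_neg = np.argmax(before <= before.min(axis=1, keepdims=True) + 1e-9, axis=1)
    p_pos = after[rows, i_pos]
    p_neg = np.minimum(before[rows, i_neg], 0.0)
    es = np.where(p_pos >= -p_neg, p_pos, p_neg)
    # magnitude tie (to rounding noise): take the deviation occurring
    # earliest in the ranked list; the negative dip sits at position - 1,
    # just before its hit
    tie = np.abs(p_pos + p_neg) <= 1e-9
    if np.any(tie):
        earlier_neg = positions[rows, i_neg] - 1 < positions[rows, i_pos]
        es = np.where(tie, np.where(earlier_neg, p_neg, p_pos), es)
    return es


def enrichment_score(ranked: RankedList, geneset: GeneSet, weight: float = 1.0,
                     min_size: int = 15, max_size: int = 500,
                     case_sensitive: bool = False) -> EnrichmentStat:
    """Weighted running-sum enrichment score of ``geneset`` on ``ranked``.

    Members absent from the ranked list are dropped (and reflected in
    ``set_size_used``); a set whose intersection falls outside
    ``[min_size, max_size]`` raises :class:`GeneSetSizeSkip`, and a set
    covering every ranked gene is a degenerate input.
    """
    pos = match_members(geneset.members, ranked.genes, case_sensitive)
    k = len(pos)
    if k == len(ranked):
        raise ValidationError(f"gene set {geneset.name!r} covers every ranked gene")
    if k < max(min_size, 1) or k > max_size:
        raise GeneSetSizeSkip(geneset.name, k, min_size, max_size)
    absw = np.abs(ranked.metrics) ** weight
    es = float(_batch_es(absw, pos[None, :])[0])
    return EnrichmentStat(es=es, hit_positions=pos, set_size_used=k)


def running_sum(ranked: RankedList, hit_positions: np.ndarray,
                weight: float = 1.0) -> np.ndarray:
    """Full running-sum profile (length N); ends at 0 by construction.

    Used for diagnostics and as an internal cross-check of the O(k) extremum
    scan; not needed to compute ES.
    """
    N = len(ranked)
    k = len(hit_positions)
    absw = np.abs(ranked.metrics) ** weight
    steps = np.full(N, -1.0 / (N - k))
    w = absw[hit_positions]
    nr = w.sum()
    if nr == 0:
        steps[hit_positions] = 1.0 / k
    else:
        steps[hit_positions] = w / nr
    return np.cumsum(steps)


# ---------------------------------------------------------------------------
# permutation nulls
# ---------------------------------------------------------------------------

def _random_subsets(rng: np.random.Generator, n_perm: int, N: int, k: int) -> np.ndarray:
    """(n_perm, k) sorted random k-subsets of range(N), without replacement."""
    idx = np.argsort(rng.random((n_perm, N)), axis=1)[:, :k]
    return np.sort(idx, axis=1)


def _random_member_positions(rng: np.random.Generator, n_perm: int,
                             ranked: RankedList, k: int) -> np.ndarray:
    """Random same-size member sets as sorted ranked-list positions.

    Subsets are drawn in a canonical (lexicographic) gene order and then
    mapped to positions, so the *gene sets* drawn depend only on the seed and
    the gene universe — swapping the comparison's classes reverses the list
    but reproduces the same null member sets, which keeps NES exactly
    antisymmetric under a fixed seed.
    """
    canon_pos = np.argsort(np.asarray(ranked.genes))
    idx = _random_subsets(rng, n_perm, len(ranked), k)
    return np.sort(canon_pos[idx], axis=1)


def null_enrichment_scores(mode: str, n_perm: int, seed, *,
                           ranked: RankedList | None = None,
                           set_size: int | None = None,
                           dataset: ExpressionDataset | None = None,
                           geneset: GeneSet | None = None,
                           weight: float = 1.0,
                           min_replicates_override: bool = False,
                           case_sensitive: bool = False) -> np.ndarray:
    """Null ES distribution for one gene set / comparison cell.

    ``mode="geneset"``: ES of ``n_perm`` random same-size member sets drawn
    without replacement from the ranked genes (needs ``ranked`` and
    ``set_size``).  ``mode="sample"``: ES of the true set after shuffling the
    pair's sample labels preserving group sizes and re-ranking (needs
    ``dataset``, ``geneset`` and the pair stored on ``ranked``); every class
    must have at least 5 replicates unless ``min_replicates_override``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "geneset":
        if ranked is None or set_size is None:
            raise ValidationError("geneset-permutation null needs a ranked list and a set size")
        N = len(ranked)
        if not 0 < set_size < N:
            raise ValidationError(f"set size {set_size} out of range for {N} ranked genes")
        absw = np.abs(ranked.metrics) ** weight
        return _batch_es(absw, _random_member_positions(rng, n_perm, ranked, set_size))
    if mode == "sample":
        if dataset is None or geneset is None or ranked is None:
            raise ValidationError("sample-permutation null needs dataset, geneset and ranked list")
        pair = (ranked.class_left, ranked.class_right)
        if not min_replicates_override:
            for label in pair:
                r = dataset.replicate_count(label)
                if r < MIN_SAMPLE_PERM_REPLICATES:
                    raise ReplicateCountError(
                        f"sample permutation requires at least "
                        f"{MIN_SAMPLE_PERM_REPLICATES} replicates per class; "
                        f"class {label!r} has {r}"
                    )
        lcols = dataset.samples_of(pair[0])
        rcols = dataset.samples_of(pair[1])
        cols = np.concatenate([lcols, rcols])
        nl = len(lcols)
        members = match_members(geneset.members, dataset.identifiers, case_sensitive)
        member_mask = np.zeros(dataset.n_genes, dtype=bool)
        member_mask[members] = True
        out = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(cols)
            metrics = _snr_metrics(dataset, perm[:nl], perm[nl:])
            order = np.argsort(-metrics, kind="stable")
            pos = np.flatnonzero(member_mask[order])
            absw = np.abs(metrics[order]) ** weight
            out[i] = _batch_es(absw, pos[None, :])[0]
        return out
    raise ValidationError(f"unknown permutation mode {mode!r}; use 'geneset' or 'sample'")


def normalize_es(es: float, null_es: np.ndarray) -> tuple[float | None, np.ndarray]:
    """NES = ES divided by the mean magnitude of same-sign null scores.

    The null itself is normalized the same way per sign (so its same-sign
    mean magnitude is 1 by construction).  When no null score shares the sign
    of ``es`` the NES is undefined and ``None`` is returned.
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValidationError("empty null ES vector")
    pos = null_es[null_es > 0]
    neg = null_es[null_es < 0]
    pos_mean = pos.mean() if pos.size else np.nan
    neg_mean = np.abs(neg).mean() if neg.size else np.nan
    norm = null_es.copy()
    if pos.size:
        norm[null_es > 0] = null_es[null_es > 0] / pos_mean
    if neg.size:
        norm[null_es < 0] = null_es[null_es < 0] / neg_mean
    if es > 0:
        nes = es / pos_mean if pos.size else None
    elif es < 0:
        nes = -(abs(es) / neg_mean) if neg.size else None
    else:
        nes = 0.0
    return nes, norm


def nominal_pvalue(es: float, null_es: np.ndarray) -> float:
    """Never-zero nominal p: (b+1)/(m+1) over same-sign null scores."""
    null_es = np.asarray(null_es, dtype=float)
    if es >= 0:
        same = null_es[null_es >= 0]
    else:
        same = null_es[null_es < 0]
    b = int((np.abs(same) >= abs(es)).sum())
    return (b + 1) / (same.size + 1)
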