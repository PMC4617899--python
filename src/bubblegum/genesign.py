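"""Molecular signature extraction.

A *signature* is the list of genes expressed more highly in a set of test
phenotype classes than in reference classes, selected by one of five
statistics (a min/max ratio, pooled or minimal-pairwise mean ratios, pooled
or minimal-pairwise signal-to-noise ratios), with one-sided permutation
p-values and Benjamini-Hochberg / Benjamini-Yekutieli FDR control.

Permutation nulls shuffle the sample -> class assignment restricted to the
samples of the contrast, preserving each class's replicate count.  The
p-value estimator is the never-zero ``(b + 1) / (m + 1)`` form, so no p-value
is ever reported as 0; when the number of distinct assignments does not
exceed the requested permutation count the null is enumerated exhaustively.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import ExpressionDataset, ReplicateCountError, ValidationError

__all__ = [
    "SignatureMethod",
    "ContrastSpec",
    "Signature",
    "score_genes",
    "permutation_pvalues",
    "adjust_pvalues",
    "extract_signature",
    "absolute_signatures",
    "signature_table",
    "floored_sd",
]


class SignatureMethod(str, Enum):
    MIN_VS_MAX = "min-vs-max"
    MEAN_RATIO = "mean-ratio"
    MIN_PAIRWISE_MEAN_RATIO = "min-pairwise-mean-ratio"
    SNR = "snr"
    MIN_PAIRWISE_SNR = "min-pairwise-snr"

    @property
    def is_ratio(self) -> bool:
        return self in (
            SignatureMethod.MIN_VS_MAX,
            SignatureMethod.MEAN_RATIO,
            SignatureMethod.MIN_PAIRWISE_MEAN_RATIO,
        )

    @property
    def supports_permutation(self) -> bool:
        return self is not SignatureMethod.MIN_VS_MAX


@dataclass(frozen=True)
class ContrastSpec:
    """Test classes versus reference classes.

    ``mode`` is ``"absolute"`` when the reference is every other class in the
    dataset and ``"relative"`` when the user picked the reference subset.
    """

    test_classes: tuple[str, ...]
    ref_classes: tuple[str, ...]
    mode: str = "relative"

    def __post_init__(self) -> None:
        if not self.test_classes or not self.ref_classes:
            raise ValidationError("contrast needs at least one test and one reference class")
        if set(self.test_classes) & set(self.ref_classes):
            raise ValidationError("test and reference classes must be disjoint")
        if self.mode not in ("absolute", "relative"):
            raise ValidationError(f"unknown contrast mode: {self.mode!r}")

    def validate_against(self, dataset: ExpressionDataset) -> None:
        known = set(dataset.classes)
        unknown = [c for c in (*self.test_classes, *self.ref_classes) if c not in known]
        if unknown:
            raise ValidationError(f"contrast names classes absent from the dataset: {unknown}")
        if self.mode == "absolute":
            expected = known - set(self.test_classes)
            if set(self.ref_classes) != expected:
                raise ValidationError(
                    "absolute contrasts must use all non-test classes as reference"
                )

    @staticmethod
    def absolute(dataset: ExpressionDataset, test: str | Sequence[str]) -> "ContrastSpec":
        test_t = (test,) if isinstance(test, str) else tuple(test)
        ref = tuple(c for c in dataset.classes if c not in test_t)
        return ContrastSpec(test_classes=test_t, ref_classes=ref, mode="absolute")


@dataclass
class Signature:
    """Genes passing the thresholds for one contrast, sorted by score."""

    name: str
    contrast: ContrastSpec
    method: SignatureMethod
    rows: pd.DataFrame  # columns: gene, score, p, fdr, n_test, n_ref
    fold_threshold: float
    fdr_threshold: float | None
    empty: bool
    n_perm: int | None = None
    seed: int | None = None
    procedure: str | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.rows["gene"])

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def floored_sd(sum_: np.ndarray, sumsq: np.ndarray, n: int, mean: np.ndarray,
               delta: float) -> np.ndarray:
    """Sample standard deviation (ddof=1) with a relative floor.

    The floor ``sd >= max(0.2 * |mean|, 0.2 * delta)`` (``delta`` = smallest
    positive value in the matrix) prevents zero denominators for flat genes,
    following the GSEA-ecosystem signal-to-noise convention.
    """
    var = (sumsq - n * mean**2) / (n - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    return np.maximum(sd, np.maximum(0.2 * np.abs(mean), 0.2 * delta))


def _smallest_positive(values: np.ndarray) -> float:
    pos = values[values > 0]
    return float(pos.min()) if pos.size else 1.0


def _check_positive(dataset: ExpressionDataset, cols: np.ndarray, method: SignatureMethod) -> None:
    sub = dataset.values[:, cols]
    bad = np.argwhere(sub <= 0)
    if bad.size:
        g, s = bad[0]
        raise ValidationError(
            f"{method.value} requires strictly positive intensities; gene "
            f"{dataset.identifiers[g]!r}, sample {dataset.sample_names[cols[s]]!r} "
            f"has value {sub[g, s]}"
        )


def _involved(dataset: ExpressionDataset, contrast: ContrastSpec):
    """Column indices (class-blocked), per-class sizes, and class count split."""
    classes = [*contrast.test_classes, *contrast.ref_classes]
    per_class = [dataset.samples_of(c) for c in classes]
    sizes = [len(ix) for ix in per_class]
    cols = np.concatenate(per_class)
    return classes, cols, sizes, len(contrast.test_classes)


def _perm_scores(X: np.ndarray, masks: list[np.ndarray], sizes: list[int],
                 n_test_classes: int, method: SignatureMethod, delta: float) -> np.ndarray:
    """Scores (genes x permutations) given per-class membership masks.

    ``masks[c]`` has shape (n_involved, P) with ones marking the samples
    assigned to class ``c`` in each permutation.
    """
    sums = [X @ m for m in masks]
    t_idx = range(n_test_classes)
    r_idx = range(n_test_classes, len(masks))
    if method is SignatureMethod.MEAN_RATIO:
        tm = sum(sums[i] for i in t_idx) / sum(sizes[i] for i in t_idx)
        rm = sum(sums[i] for i in r_idx) / sum(sizes[i] for i in r_idx)
        return tm / rm
    if method is SignatureMethod.MIN_PAIRWISE_MEAN_RATIO:
        means = [sums[i] / sizes[i] for i in range(len(masks))]
        out = None
        for i in t_idx:
            for j in r_idx:
                r = means[i] / means[j]
                out = r if out is None else np.minimum(out, r)
        return out
    X2 = X**2
    sumsqs = [X2 @ m for m in masks]
    if method is SignatureMethod.SNR:
        nt = sum(sizes[i] for i in t_idx)
        nr = sum(sizes[i] for i in r_idx)
        ts, tss = sum(sums[i] for i in t_idx), sum(sumsqs[i] for i in t_idx)
        rs, rss = sum(sums[i] for i in r_idx), sum(sumsqs[i] for i in r_idx)
        tm, rm = ts / nt, rs / nr
        return (tm - rm) / (floored_sd(ts, tss, nt, tm, delta)
                            + floored_sd(rs, rss, nr, rm, delta))
    if method is SignatureMethod.MIN_PAIRWISE_SNR:
        means = [sums[i] / sizes[i] for i in range(len(masks))]
        sds = [floored_sd(sums[i], sumsqs[i], sizes[i], means[i], delta)
               for i in range(len(masks))]
        out = None
        for i in t_idx:
            for j in r_idx:
                s = (means[i] - means[j]) / (sds[i] + sds[j])
                out = s if out is None else np.minimum(out, s)
        return out
    raise ValidationError(f"no permutation scoring for method {method.value}")


def _identity_masks(sizes: list[int]) -> list[np.ndarray]:
    n = sum(sizes)
    masks = []
    off = 0
    for s in sizes:
        m = np.zeros((n, 1))
        m[off:off + s, 0] = 1.0
        off += s
        masks.append(m)
    return masks


def _check_replicates(sizes: list[int], n_test_classes: int, method: SignatureMethod) -> None:
    if method in (SignatureMethod.SNR, SignatureMethod.MIN_PAIRWISE_SNR):
        pooled = method is SignatureMethod.SNR
        if pooled:
            nt = sum(sizes[:n_test_classes])
            nr = sum(sizes[n_test_classes:])
            if nt < 2 or nr < 2:
                raise ReplicateCountError(
                    "signal-to-noise needs at least 2 replicates in the pooled "
                    f"test ({nt}) and reference ({nr}) groups"
                )
        else:
            for k, s in enumerate(sizes):
                if s < 2:
                    raise ReplicateCountError(
                        f"pairwise signal-to-noise needs >= 2 replicates per class; "
                        f"class #{k} has {s}"
                    )


def score_genes(dataset: ExpressionDataset, contrast: ContrastSpec,
                method: SignatureMethod) -> np.ndarray:
    """One observed score per gene for the given contrast and statistic."""
    contrast.validate_against(dataset)
    classes, cols, sizes, ntc = _involved(dataset, contrast)
    if method.is_ratio:
        _check_positive(dataset, cols, method)
    _check_replicates(sizes, ntc, method)
    X = dataset.values[:, cols]
    if method is SignatureMethod.MIN_VS_MAX:
        nt = sum(sizes[:ntc])
        return X[:, :nt].min(axis=1) / X[:, nt:].max(axis=1)
    delta = _smallest_positive(dataset.values)
    return _perm_scores(X, _identity_masks(sizes), sizes, ntc, method, delta)[:, 0]


# ---------------------------------------------------------------------------
# permutation p-values
# ---------------------------------------------------------------------------

def _n_distinct_assignments(sizes: list[int]) -> int:
    n = sum(sizes)
    d = math.factorial(n)
    for s in sizes:
        d //= math.factorial(s)
    return d


def _exhaustive_index_matrix(n: int, sizes: list[int]) -> np.ndarray:
    """All distinct assignments as rows of position indices, class-blocked."""
    rows: list[list[int]] = []

    def rec(remaining: tuple[int, ...], k: int, acc: list[int]):
        if k == len(sizes):
            rows.append(acc)
            return
        for combo in itertools.combinations(remaining, sizes[k]):
            rest = tuple(x for x in remaining if x not in combo)
            rec(rest, k + 1, acc + list(combo))

    rec(tuple(range(n)), 0, [])
    return np.array(rows, dtype=int)


def _masks_from_index(idx: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
    """Per-class (n x P) membership masks from a (P x n) index matrix."""
    P, n = idx.shape
    masks = []
    off = 0
    for s in sizes:
        m = np.zeros((P, n))
        np.put_along_axis(m, idx[:, off:off + s], 1.0, axis=1)
        masks.append(m.T)
        off += s
    return masks


def permutation_pvalues(dataset: ExpressionDataset, contrast: ContrastSpec,
                        method: SignatureMethod, n_perm: int, seed: int,
                        pooled: bool = False,
                        observed: np.ndarray | None = None) -> np.ndarray:
    """One-sided permutation p-values (test > reference) per gene.

    ``b`` counts permuted scores >= the observed score; ``p = (b+1)/(m+1)``
    so the smallest reachable value is ``1/(m+1)``, never 0.  When the number
    of distinct sample -> class assignments is at most ``n_perm`` the null is
    enumerated exhaustively (identity assignment included).  By default each
    gene is compared to its own permuted scores; ``pooled=True`` compares it
    to the permuted scores of all genes combined.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not method.supports_permutation:
        raise ValidationError("min-vs-max has no permutation path")
    contrast.validate_against(dataset)
    classes, cols, sizes, ntc = _involved(dataset, contrast)
    if method.is_ratio:
        _check_positive(dataset, cols, method)
    _check_replicates(sizes, ntc, method)
    X = dataset.values[:, cols]
    delta = _smallest_positive(dataset.values)
    if observed is None:
        observed = _perm_scores(X, _identity_masks(sizes), sizes, ntc, method, delta)[:, 0]

    n = sum(sizes)
    G = X.shape[0]
    b = np.zeros(G, dtype=np.int64)
    obs_sorted = np.sort(observed) if pooled else None

    def accumulate(idx_matrix: np.ndarray) -> None:
        nonlocal b
        scores = _perm_scores(X, _masks_from_index(idx_matrix, sizes), sizes, ntc,
                              method, delta)
        if pooled:
            flat = np.sort(scores, axis=None)
            # for each observed value: permuted scores >= it, across all genes
            b += flat.size - np.searchsorted(flat, observed, side="left")
        else:
            b += (scores >= observed[:, None]).sum(axis=1)

    d = _n_distinct_assignments(sizes)
    if d <= n_perm:
        idx = _exhaustive_index_matrix(n, sizes)
        m = d
        chunk = max(1, int(3e7) // max(G, 1))
        for lo in range(0, d, chunk):
            accumulate(idx[lo:lo + chunk])
    else:
        m = n_perm
        rng = np.random.default_rng(seed)
        chunk = max(64, min(n_perm, int(3e7) // max(G, 1)))
        done = 0
        while done < n_perm:
            P = min(chunk, n_perm - done)
            idx = np.argsort(rng.random((P, n)), axis=1)
            accumulate(idx)
            done += P
    denom = (m * G if pooled else m) + 1
    return (b + 1) / denom


def adjust_pvalues(p: np.ndarray, procedure: str = "BY") -> np.ndarray:
    """Benjamini-Hochberg (``"BH"``) or Benjamini-Yekutieli (``"BY"``) step-up
    adjusted p-values, in the input order, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    method = {"BH": "fdr_bh", "BY": "fdr_by"}.get(procedure.upper())
    if method is None:
        raise ValidationError(f"unknown procedure {procedure!r}; use 'BH' or 'BY'")
    return multipletests(p, method=method)[1]


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

def extract_signature(dataset: ExpressionDataset, contrast: ContrastSpec,
                      method: SignatureMethod, fold_threshold: float,
                      fdr_threshold: float | None = None, n_perm: int = 1000,
                      seed: int = 0, procedure: str = "BY",
                      pooled_null: bool = False,
                      name: str | None = None) -> Signature:
    """Genes with score strictly above ``fold_threshold`` (and, for
    permutation-based methods with ``fdr_threshold`` set, adjusted p strictly
    below it), sorted by score descending with input-order tie-breaks."""
    if fold_threshold <= 0:
        raise ValidationError("fold_threshold must be positive")
    if fdr_threshold is not None:
        if not method.supports_permutation:
            raise ValidationError("min-vs-max carries no p-values; fdr_threshold is not applicable")
        if not 0 < fdr_threshold <= 1:
            raise ValidationError("fdr_threshold must lie in (0, 1]")
    contrast.validate_against(dataset)
    scores = score_genes(dataset, contrast, method)
    p = fdr = None
    if method.supports_permutation and fdr_threshold is not None:
        p = permutation_pvalues(dataset, contrast, method, n_perm, seed,
                                pooled=pooled_null, observed=scores)
        fdr = adjust_pvalues(p, procedure)
    keep = scores > fold_threshold
    if fdr is not None:
        keep &= fdr < fdr_threshold
    order = np.argsort(-scores, kind="stable")
    order = order[keep[order]]
    n_test = sum(dataset.replicate_count(c) for c in contrast.test_classes)
    n_ref = sum(dataset.replicate_count(c) for c in contrast.ref_classes)
    rows = pd.DataFrame({
        "gene": [dataset.identifiers[i] for i in order],
        "score": scores[order],
        "p": p[order] if p is not None else np.nan,
        "fdr": fdr[order] if fdr is not None else np.nan,
        "n_test": n_test,
        "n_ref": n_ref,
    })
    if name is None:
        name = f"{'_'.join(contrast.test_classes)}_vs_{'_'.join(contrast.ref_classes)}_{method.value}"
    return Signature(
        name=name, contrast=contrast, method=method, rows=rows,
        fold_threshold=fold_threshold, fdr_threshold=fdr_threshold,
        empty=len(rows) == 0, n_perm=n_perm if p is not None else None,
        seed=seed if p is not None else None,
        procedure=procedure if fdr is not None else None,
    )


def absolute_signatures(dataset: ExpressionDataset, method: SignatureMethod,
                        fold_threshold: float, fdr_threshold: float | None = None,
                        n_perm: int = 1000, seed: int = 0, procedure: str = "BY",
                        pooled_null: bool = False) -> list[Signature]:
    """One absolute signature per phenotype class (test = class, reference =
    all other classes).  An empty signature is a legal result, not an error."""
    if len(dataset.classes) < 2:
        raise ValidationError("absolute signatures need at least 2 phenotype classes")
    out = []
    for c in dataset.classes:
        contrast = ContrastSpec.absolute(dataset, c)
        out.append(extract_signature(
            dataset, contrast, method, fold_threshold, fdr_threshold,
            n_perm=n_perm, seed=seed, procedure=procedure, pooled_null=pooled_null,
            name=f"{c}_absolute_{method.value}",
        ))
    return out


def signature_table(signature: Signature, dataset: ExpressionDataset) -> pd.DataFrame:
    """Result table for export: statistics columns followed by the normalized
    expression of every sample, for direct use in third-party tools."""
    idx = dataset.gene_index()
    rows = signature.rows.copy()
    expr = np.array([dataset.values[idx[g]] for g in rows["gene"]]).reshape(
        len(rows), dataset.n_samples)
    for j, s in enumerate(dataset.sample_names):
        rows[s] = expr[:, j] if len(rows) else np.array([])
    return rows
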