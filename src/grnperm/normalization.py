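"""Library-size normalization and low-count filtering.

Two between-sample normalization strategies are provided: the trimmed mean
of M-values (TMM, the edgeR approach) and the median-of-ratios strategy of
DESeq2. Both estimate one positive scaling factor per sample; normalized
values are expressed on a fixed per-million scale so that the result is
exactly invariant to per-column depth multipliers:

* TMM: ``x / (factor * library_size) * 1e6`` (edgeR's CPM convention);
* median-of-ratios: ``x / factor * 1e6 / geomean(library sizes)`` (DESeq2
  normalized counts, rescaled once by a data-wide constant).

Low-abundance genes are filtered on their total count across samples before
factors are estimated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, SizeFactors

__all__ = [
    "filter_low_counts",
    "size_factors_median_of_ratios",
    "size_factors_tmm",
    "apply_normalization",
    "normalize",
    "log_transform",
]

#: output scale for normalized values (per-million convention)
CPM_SCALE = 1e6


def filter_low_counts(counts: CountMatrix, threshold: float) -> CountMatrix:
    """Drop genes whose total count summed over all samples is below ``threshold``.

    Genes with row sum >= threshold are kept; samples are untouched. A
    threshold that removes every gene is an error.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if counts.normalized:
        warnings.warn("filtering low counts on already-normalized values")
    # reduce over a C-order array: the result must not depend on the
    # DataFrame's internal block layout (file-read vs array-built)
    keep = np.ascontiguousarray(counts.values.to_numpy()).sum(axis=1) >= threshold
    if not keep.any():
        raise ValueError(
            f"low-count threshold {threshold} removes every gene; lower it"
        )
    return CountMatrix(values=counts.values.loc[keep], normalized=counts.normalized)


def size_factors_median_of_ratios(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors (the DESeq2 strategy).

    For every gene with strictly positive counts in all samples, a reference
    level is the geometric mean of its counts across samples; the factor of a
    sample is the median over those genes of count / reference.
    """
    x = np.ascontiguousarray(counts.values.to_numpy(dtype=float))
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "median-of-ratios needs at least one gene with positive counts in "
            "every sample; filter low-count genes first"
        )
    pos = x[all_positive]
    log_ref = np.log(pos).mean(axis=1)  # log geometric mean per gene
    ratios = np.exp(np.log(pos) - log_ref[:, None])
    factors = np.median(ratios, axis=0)
    return SizeFactors(
        factors=pd.Series(factors, index=counts.values.columns),
        method="median_of_ratios",
    )


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference sample."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    o = obs[keep] / n_obs
    r = ref[keep] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic binomial variance of M (delta method), used as 1/weight
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (
        n_ref * ref[keep]
    )
    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not kept.any():
        warnings.warn(
            "no genes survive TMM double trimming; falling back to the "
            "untrimmed weighted mean of M values"
        )
        kept = np.ones_like(kept)
    return float(np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept]))


def size_factors_tmm(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> SizeFactors:
    """Trimmed-mean-of-M-values size factors.

    The reference sample is the one whose upper-quartile depth-scaled count is
    closest to the mean upper quartile. Against it, every sample's factor is
    2 to the precision-weighted mean of its gene-wise log2 expression ratios
    (M values), after trimming the most extreme ``trim_m`` fraction of M and
    ``trim_a`` fraction of average abundance (A) from each tail. Factors are
    rescaled so their geometric mean is 1.
    """
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    x = np.ascontiguousarray(counts.values.to_numpy(dtype=float))
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    q75 = np.array([np.quantile(x[:, j], 0.75) for j in range(x.shape[1])]) / lib
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    log2f = np.array(
        [
            0.0
            if j == ref_idx
            else _tmm_pair_factor(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors = 2.0**log2f
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return SizeFactors(
        factors=pd.Series(factors, index=counts.values.columns), method="tmm"
    )


def apply_normalization(counts: CountMatrix, factors: SizeFactors) -> CountMatrix:
    """Scale each sample by its size factor; returns a normalized matrix.

    TMM factors rescale effective library sizes, so values become counts per
    million of the effective library; median-of-ratios values are DESeq2
    normalized counts on a fixed per-million scale (see module docstring).
    """
    if list(factors.factors.index) != counts.sample_ids:
        raise ValueError("size factors and count matrix disagree on samples")
    f = factors.factors.to_numpy(dtype=float)
    x = np.ascontiguousarray(counts.values.to_numpy(dtype=float))  # layout-independent sums
    lib = x.sum(axis=0)
    if factors.method == "tmm":
        arr = x / (f * lib) * CPM_SCALE
    else:
        geo_lib = np.exp(np.mean(np.log(lib)))
        arr = x / f * (CPM_SCALE / geo_lib)
    values = pd.DataFrame(arr, index=counts.values.index, columns=counts.values.columns)
    return CountMatrix(values=values, normalized=True)


def log_transform(counts: CountMatrix) -> CountMatrix:
    """log2(1 + x) transform, the default input scale for forest fitting.

    Variance-reduction splits on raw count-scale values are dominated by the
    few highest-expression samples; the log makes importance estimation
    sensitive across the whole dynamic range. Rank-based steps (regulator
    grouping) are invariant to this transform.
    """
    return CountMatrix(values=np.log2(1.0 + counts.values), normalized=counts.normalized)


def normalize(
    counts: CountMatrix,
    method: str = "tmm",
    low_count_threshold: float | None = None,
) -> tuple[CountMatrix, SizeFactors | None]:
    """Filter low-count genes, then normalize with the chosen method.

    ``low_count_threshold=None`` applies the default of 10 x n_samples.
    ``method="none"`` only filters and flags the matrix as normalized.
    Returns the normalized matrix and the size factors (None for "none").
    """
    if low_count_threshold is None:
        low_count_threshold = 10.0 * counts.n_samples
    filtered = filter_low_counts(counts, low_count_threshold)
    if method == "none":
        return CountMatrix(values=filtered.values.copy(), normalized=True), None
    if method == "tmm":
        factors = size_factors_tmm(filtered)
    elif method == "median_of_ratios":
        factors = size_factors_median_of_ratios(filtered)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return apply_normalization(filtered, factors), factors
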