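"""Normalization and per-gene summary statistics.

Implements the quantities every downstream stage consumes: median-of-ratios
library size factors, baseMean (mean of size-factor-normalized counts), FPKM,
group fold-changes with a pseudocount, expression prevalence, and the qPCR
2^-ddCt relative quantity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "size_factors",
    "base_mean",
    "fpkm",
    "fold_change",
    "prevalence",
    "ddct_relative_quantity",
]


def _values(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else pd.DataFrame(matrix)


def size_factors(counts) -> pd.Series:
    """Median-of-ratios library size factors.

    For each sample s, sf_s = median over reference genes g of
    counts_gs / geomean_g, where the reference set is the genes with strictly
    positive counts in every sample (the classic median-of-ratios reference).

    Raises
    ------
    ValueError
        If no gene has all-positive counts ("no reference genes").
    """
    v = _values(counts)
    arr = v.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValueError("no reference genes: no gene has positive counts in all samples")
    logs = np.log(arr[ref])
    log_geomean = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(sf, index=v.columns, name="size_factor")


def normalized_counts(counts, factors: pd.Series | None = None):
    """Counts divided by per-sample size factors."""
    v = _values(counts)
    if factors is None:
        factors = size_factors(counts)
    out = v / factors.reindex(v.columns)
    if isinstance(counts, ExpressionMatrix):
        return counts.with_unit(out, "normalized")
    return out


def base_mean(counts, factors: pd.Series | None = None) -> pd.Series:
    """Per-gene mean of size-factor-normalized counts over all samples."""
    v = _values(counts)
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(v.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    return (v / factors).mean(axis=1).rename("base_mean")


def fpkm(counts, lengths_bp, library_sizes: pd.Series | None = None):
    """Fragments per kilobase of exon model per million mapped reads.

    FPKM_gs = counts_gs * 1e9 / (length_g * N_s). ``library_sizes`` defaults
    to the column sums of the count matrix.
    """
    v = _values(counts)
    lengths = pd.Series(lengths_bp).reindex(v.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")
    if library_sizes is None:
        library_sizes = v.sum(axis=0)
    library_sizes = pd.Series(library_sizes).reindex(v.columns)
    if (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes <= 0][0]
        raise ValueError(f"library size of sample {bad!r} is not positive")
    out = v.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)
    if isinstance(counts, ExpressionMatrix):
        return counts.with_unit(out, "fpkm")
    return out


def fold_change(matrix, group_a, group_b, pseudocount: float = 0.5) -> pd.Series:
    """Per-gene ratio of group means: (mean_a + eps) / (mean_b + eps).

    The pseudocount guards subtype-exclusive genes whose reference group mean
    is zero. Groups must be non-empty and disjoint.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("fold_change groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("fold_change groups overlap")
    v = _values(matrix)
    mean_a = v[group_a].mean(axis=1)
    mean_b = v[group_b].mean(axis=1)
    return ((mean_a + pseudocount) / (mean_b + pseudocount)).rename("fold_change")


def prevalence(matrix, group, threshold: float) -> pd.Series:
    """Fraction of ``group`` samples with value strictly above ``threshold``."""
    group = list(group)
    if not group:
        raise ValueError("prevalence group must be non-empty")
    v = _values(matrix)
    return (v[group] > threshold).mean(axis=1).rename("prevalence")


def ddct_relative_quantity(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative quantity by the ddCt method: RQ = 2^-ddCt.

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator),
    with the reference gene (e.g. GAPDH) as internal control.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))
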