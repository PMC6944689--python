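"""Cis-neighborhood analysis: window queries, neighbor co-expression, and
promoter-methylation group comparison.

The neighborhood of a focal gene is every gene whose interval intersects
[focal.start - window, focal.end + window) on the focal chromosome (0-based
half-open, strand-agnostic, gene-body anchored). Co-expression is computed on
log2(FPKM + 1) by default; methylation is compared as the share of beta values
above a threshold plus a Mann-Whitney test on per-sample mean beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneAnnotation

__all__ = ["NeighborSet", "find_neighbors", "neighbor_correlation", "methylation_compare"]


@dataclass
class NeighborSet:
    focal_id: str
    window_bp: int
    neighbor_ids: list = field(default_factory=list)  # ordered by genomic start

    def __iter__(self):
        return iter(self.neighbor_ids)

    def __len__(self):
        return len(self.neighbor_ids)


def find_neighbors(
    annotation: GeneAnnotation, focal_id: str, window_bp: int = 1_000_000, anchor: str = "body"
) -> NeighborSet:
    """Genes intersecting the focal gene's +-window on its chromosome.

    ``anchor="body"`` (default) extends the window from the gene body
    ([start - w, end + w)); ``anchor="tss"`` centers it on the 5' end
    (strand-aware). The focal gene itself is excluded.
    """
    if focal_id not in annotation:
        raise KeyError(f"unknown focal gene {focal_id!r}")
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    t = annotation.table
    focal = t.loc[focal_id]
    if anchor == "body":
        win_start, win_end = focal["start"] - window_bp, focal["end"] + window_bp
    elif anchor == "tss":
        tss = focal["end"] - 1 if focal["strand"] == "-" else focal["start"]
        win_start, win_end = tss - window_bp, tss + window_bp
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    same = t[t["chrom"] == focal["chrom"]]
    hit = (same["start"] < win_end) & (same["end"] > win_start)
    ids = same.index[hit].difference([focal_id])
    ordered = list(same.loc[ids].sort_values(["start", "end"]).index)
    return NeighborSet(focal_id, int(window_bp), ordered)


def neighbor_correlation(
    matrix: ExpressionMatrix,
    focal_id: str,
    neighbors,
    method: str = "pearson",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Correlation of each neighbor's expression with the focal gene.

    Expression is log2(x + 1)-transformed by default to stabilize variance.
    Constant vectors give an undefined correlation, reported as missing.
    """
    v = matrix.values if isinstance(matrix, ExpressionMatrix) else pd.DataFrame(matrix)
    ids = list(neighbors)
    if v.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    if focal_id not in v.index:
        raise KeyError(f"focal gene {focal_id!r} not in expression matrix")
    data = np.log2(v + 1.0) if log_transform else v
    x = data.loc[focal_id].to_numpy(dtype=float)
    rows = []
    for nid in ids:
        y = data.loc[nid].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"constant expression for {nid!r} or focal; correlation undefined")
            rows.append((nid, np.nan, np.nan))
            continue
        if method == "pearson":
            r, p = stats.pearsonr(x, y)
        elif method == "spearman":
            r, p = stats.spearmanr(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((nid, float(r), float(p)))
    return pd.DataFrame(rows, columns=["gene_id", "r", "p_value"]).set_index("gene_id")


def methylation_compare(
    betas: pd.DataFrame, group_a, group_b, methylated_threshold: float = 0.3
) -> dict:
    """Methylated fraction per group and a rank test on per-sample mean beta.

    fraction = share of (probe, sample) beta values strictly above the
    threshold within each group; the p-value is a two-sided Mann-Whitney test
    comparing per-sample mean beta between groups.
    """
    group_a, group_b = list(group_a), list(group_b)
    if betas.shape[0] < 1:
        raise ValueError("need at least one probe")
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    arr = betas.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    a, b = betas[group_a], betas[group_b]
    frac_a = float((a.to_numpy() > methylated_threshold).mean())
    frac_b = float((b.to_numpy() > methylated_threshold).mean())
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    pooled = np.concatenate([mean_a, mean_b])
    if np.all(pooled == pooled[0]):
        p = 1.0  # fully tied: no evidence of a shift
        u = len(mean_a) * len(mean_b) / 2.0
    else:
        res = stats.mannwhitneyu(mean_a, mean_b, alternative="two-sided")
        u, p = float(res.statistic), float(res.pvalue)
    return {
        "fraction_methylated_a": frac_a,
        "fraction_methylated_b": frac_b,
        "U": u,
        "p_value": p,
        "threshold": methylated_threshold,
    }
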