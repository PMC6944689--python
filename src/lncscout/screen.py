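"""Multi-criteria candidate screen for subtype-specific lncRNAs.

Reduces a genome-wide table to candidates that are (i) of lncRNA biotype,
(ii) overexpressed in the target subtype versus normal tissue and versus each
other tumor subtype (>min_fc on size-factor-normalized means), (iii) not
low-abundance (baseMean >= min_base_mean), (iv) expressed (FPKM > threshold)
in at least ``min_patient_prevalence`` of target-subtype patients, (v)
expressed in fewer than ``max_other_subtype_prevalence`` of patients of every
other tumor subtype, and (vi) expressed in at least ``min_expressing_cell_lines``
target-subtype cell lines. Normal-like (NL) samples are excluded from every
contrast by default. Every gene keeps its full metric record for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import exprcore
from .containers import ExpressionMatrix, GeneAnnotation

__all__ = ["ScreenThresholds", "CandidateTable", "run_candidate_screen", "top_expressed"]

TUMOR_SUBTYPES = ("BL", "HER2", "LA", "LB")

FILTER_FLAGS = (
    "biotype",
    "fc_vs_normal",
    "fc_vs_other_subtypes",
    "base_mean",
    "target_prevalence",
    "other_prevalence",
    "cell_lines",
)


@dataclass(frozen=True)
class ScreenThresholds:
    min_fc: float = 1.5
    min_base_mean: float = 0.5
    min_patient_prevalence: float = 0.10
    expressed_fpkm: float = 1.0
    max_other_subtype_prevalence: float = 0.15
    min_expressing_cell_lines: int = 2
    target_class: str = "BL"
    biotype_filter: frozenset = frozenset({"lncRNA"})
    exclude_classes: frozenset = frozenset({"NL"})
    pseudocount: float = 0.5
    pooled_other_contrast: bool = False  # FC vs pooled non-target tumors instead of each

    def __post_init__(self):
        if self.min_fc <= 0:
            raise ValueError("min_fc must be positive")
        for frac in (self.min_patient_prevalence, self.max_other_subtype_prevalence):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("prevalence thresholds must be in [0, 1]")


@dataclass
class CandidateTable:
    """Per-gene screen metrics and pass/fail flags.

    ``records`` holds one row per gene: fold-changes, baseMean, per-class
    prevalence, cell-line support, one 0/1 column per filter flag and
    ``passed_all``. ``passing`` is the subset with every flag set, ordered by
    descending fold-change versus normal.
    """

    records: pd.DataFrame
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)

    @property
    def passing(self) -> pd.DataFrame:
        sub = self.records[self.records["passed_all"] == 1]
        # descending fold-change vs normal; ties broken by gene id (stable sort)
        return sub.sort_index().sort_values("fc_vs_normal", ascending=False, kind="mergesort")

    @property
    def passing_ids(self) -> list:
        return list(self.passing.index)


def run_candidate_screen(
    patient_counts: ExpressionMatrix,
    patient_fpkm: ExpressionMatrix | None,
    cellline_fpkm: ExpressionMatrix | None,
    annotation: GeneAnnotation,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> CandidateTable:
    """Run the full filter cascade; returns all records plus the passing subset."""
    th = thresholds
    missing = set(patient_counts.gene_ids) - set(annotation.gene_ids)
    if missing:
        raise ValueError(f"annotation does not cover genes: {sorted(missing)[:5]}")
    if patient_fpkm is None:
        patient_fpkm = exprcore.fpkm(patient_counts, annotation.lengths(patient_counts.gene_ids))

    classes = patient_counts.sample_class
    present = set(classes)
    target = th.target_class
    others = [c for c in TUMOR_SUBTYPES if c != target and c not in th.exclude_classes]
    for cls in (target, "NORMAL"):
        if cls not in present:
            raise ValueError(f"no samples of class {cls!r} in patient matrix")
    others = [c for c in others if c in present]

    target_samples = patient_counts.samples_of_class(target)
    normal_samples = patient_counts.samples_of_class("NORMAL")

    sf = exprcore.size_factors(patient_counts)
    normalized = exprcore.normalized_counts(patient_counts, sf)
    norm_vals = normalized.values if isinstance(normalized, ExpressionMatrix) else normalized
    basemean = exprcore.base_mean(patient_counts, sf)

    fc_normal = exprcore.fold_change(norm_vals, target_samples, normal_samples, th.pseudocount)
    fc_other = {}
    if th.pooled_other_contrast and others:
        pooled = [s for c in others for s in patient_counts.samples_of_class(c)]
        fc_other["pooled"] = exprcore.fold_change(norm_vals, target_samples, pooled, th.pseudocount)
    else:
        for cls in others:
            fc_other[cls] = exprcore.fold_change(
                norm_vals, target_samples, patient_counts.samples_of_class(cls), th.pseudocount
            )

    prev = {
        cls: exprcore.prevalence(patient_fpkm, patient_fpkm.samples_of_class(cls), th.expressed_fpkm)
        for cls in [target] + others
        if patient_fpkm.samples_of_class(cls)
    }

    gene_index = patient_counts.gene_ids
    if cellline_fpkm is not None:
        target_lines = cellline_fpkm.samples_of_class(target)
        if target_lines:
            n_lines = (
                (cellline_fpkm.values[target_lines] > th.expressed_fpkm).sum(axis=1).reindex(gene_index).fillna(0)
            )
        else:
            warnings.warn(f"no {target!r} cell lines; cell-line filter counts 0 lines")
            n_lines = pd.Series(0, index=gene_index)
    else:
        n_lines = pd.Series(0, index=gene_index)

    biotypes = annotation.table["biotype"].reindex(gene_index)

    rec = pd.DataFrame(index=gene_index)
    rec.index.name = "gene_id"
    rec["biotype_value"] = biotypes
    rec["fc_vs_normal"] = fc_normal
    for cls, fc in fc_other.items():
        rec[f"fc_vs_{cls}"] = fc
    rec["base_mean"] = basemean
    for cls, p in prev.items():
        rec[f"prevalence_{cls}"] = p
    rec["n_expressing_cell_lines"] = n_lines.astype(int)

    # flags
    rec["flag_biotype"] = biotypes.isin(set(th.biotype_filter)).astype(int)
    rec["flag_fc_vs_normal"] = (fc_normal > th.min_fc).astype(int)
    fc_cols = [f"fc_vs_{cls}" for cls in fc_other]
    if fc_cols:
        rec["flag_fc_vs_other_subtypes"] = (rec[fc_cols] > th.min_fc).all(axis=1).astype(int)
    else:
        rec["flag_fc_vs_other_subtypes"] = 1
    rec["flag_base_mean"] = (basemean >= th.min_base_mean).astype(int)
    rec["flag_target_prevalence"] = (prev[target] >= th.min_patient_prevalence).astype(int)
    other_prev_cols = [f"prevalence_{cls}" for cls in others if cls in prev]
    if other_prev_cols:
        rec["flag_other_prevalence"] = (
            (rec[other_prev_cols] < th.max_other_subtype_prevalence).all(axis=1).astype(int)
        )
    else:
        rec["flag_other_prevalence"] = 1
    rec["flag_cell_lines"] = (rec["n_expressing_cell_lines"] >= th.min_expressing_cell_lines).astype(int)

    flag_cols = [f"flag_{name}" for name in FILTER_FLAGS]
    rec["passed_all"] = rec[flag_cols].all(axis=1).astype(int)

    if rec["flag_biotype"].sum() == 0:
        warnings.warn("no genes of the requested biotype; screen returns an empty passing set")

    return CandidateTable(rec, th)


def top_expressed(matrix: ExpressionMatrix, n: int) -> list:
    """Ids of the ``n`` genes with highest mean expression; ties by gene id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    means = matrix.values.mean(axis=1)
    if n > len(means):
        warnings.warn(f"requested {n} genes but matrix has {len(means)}; truncating")
        n = len(means)
    order = sorted(means.index, key=lambda g: (-means[g], g))
    return order[:n]
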