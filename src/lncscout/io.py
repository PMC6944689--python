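"""Readers and writers for the pipeline's text formats.

Expression TSV: genes as rows, header row of sample ids, index column gene_id.
A JSON sidecar (``<path>.meta.json``) carries the unit tag and per-sample class
labels; when absent, the caller supplies them. GTF is parsed/written as
1-based inclusive and converted to the internal 0-based half-open convention.
GMT, clinical TSV, methylation TSV and the drug-response CSV follow their
standard layouts. All readers reject duplicates and report offending ids or
line numbers.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneAnnotation

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gtf",
    "write_gtf",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_drug_csv",
    "write_drug_csv",
    "read_methylation_tsv",
    "write_methylation_tsv",
]

_FLOAT_FORMAT = "%.10g"


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)
    meta = {"unit": matrix.unit, "sample_class": matrix.sample_class.to_dict()}
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_expression_tsv(path, sample_class: pd.Series | None = None, unit: str | None = None) -> ExpressionMatrix:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty expression file")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number) or np.isnan(body.astype(float)).any():
        raise ValueError(f"{path}: non-numeric or missing cells in expression body")
    sidecar = _sidecar(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        unit = unit or meta.get("unit", "counts")
        if sample_class is None:
            sample_class = pd.Series(meta.get("sample_class", {}))
    if sample_class is None:
        # any string label satisfies the container; callers can relabel later
        sample_class = pd.Series("UNKNOWN", index=df.columns)
    return ExpressionMatrix(df, sample_class, unit or "counts")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> GeneAnnotation:
    """Parse gene features from a GTF file (1-based inclusive coordinates).

    Internal coordinates are 0-based half-open: start = start_gtf - 1,
    end = end_gtf. length_bp defaults to the genomic span.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            start_i, end_i = int(start) - 1, int(end)
            if end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: end < start")
            if strand not in {"+", "-", "."}:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append(
                dict(
                    gene_id=attr["gene_id"],
                    gene_name=attr.get("gene_name", attr["gene_id"]),
                    biotype=attr.get("gene_biotype", attr.get("gene_type", "unknown")),
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    length_bp=int(attr.get("length_bp", end_i - start_i)),
                )
            )
    if not rows:
        raise ValueError(f"{path}: no gene features found")
    table = pd.DataFrame(rows)
    dup = table["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate gene id {table['gene_id'][dup].iloc[0]!r}")
    return GeneAnnotation(table.set_index("gene_id"))


def write_gtf(annotation: GeneAnnotation, path, source: str = "lncscout") -> None:
    with open(path, "w") as fh:
        for gid, row in annotation.table.iterrows():
            attrs = (
                f'gene_id "{gid}"; gene_name "{row.get("gene_name", gid)}"; '
                f'gene_biotype "{row["biotype"]}"; length_bp "{row["length_bp"]}";'
            )
            fh.write(
                "\t".join(
                    [
                        str(row["chrom"]), source, "gene",
                        str(int(row["start"]) + 1), str(int(row["end"])),
                        ".", row["strand"], ".", attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GMT, clinical, drug, methylation, truth
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
            name, _desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            if len(set(members)) != len(members):
                raise ValueError(f"{path}:{lineno}: duplicate members in set {name!r}")
            sets[name] = members
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(gene_sets: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_clinical(path) -> pd.DataFrame:
    """Clinical TSV: sample_id, time_days, event, class."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_days", "event", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    if (df["time_days"] < 0).any():
        raise ValueError(f"{path}: negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0 or 1")
    df["time_days"] = df["time_days"].astype(float)
    df["event"] = df["event"].astype(int)
    return df.set_index("sample_id")


def write_clinical(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


def read_drug_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_line", "compound", "ic50_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["ic50_uM"] <= 0).any():
        bad = df.index[df["ic50_uM"] <= 0][0]
        raise ValueError(f"{path}: non-positive IC50 at row {bad + 2}")
    if df.duplicated(["cell_line", "compound"]).any():
        raise ValueError(f"{path}: duplicate (cell_line, compound) pair")
    return df


def write_drug_csv(table: pd.DataFrame, path) -> None:
    table[["cell_line", "compound", "ic50_uM"]].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_methylation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"{path}: beta values outside [0, 1]")
    return df


def write_methylation_tsv(betas: pd.DataFrame, path) -> None:
    out = betas.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)
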