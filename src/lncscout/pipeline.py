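"""End-to-end pipeline: screen -> survival -> enrichment -> cis -> drug screen.

``simulate_to_dir`` materializes a complete synthetic study (expression,
annotation, clinical, gene sets, drugs, methylation, truth ledger) as text
files; ``run_pipeline`` consumes such a directory (or any inputs in the same
formats) and writes one table per stage plus a JSON run manifest capturing
every threshold, seed and output checksum. Given the same inputs and seed the
outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cisreg, drugscreen, enrich, exprcore, io, simdata, survival
from .containers import ExpressionMatrix
from .screen import ScreenThresholds, run_candidate_screen

__all__ = ["PipelineConfig", "simulate_to_dir", "run_pipeline", "DEFAULT_FILENAMES"]

DEFAULT_FILENAMES = {
    "patient_counts": "patient_counts.tsv",
    "patient_fpkm": "patient_fpkm.tsv",
    "cellline_fpkm": "cellline_fpkm.tsv",
    "gtf": "genes.gtf",
    "clinical": "clinical.tsv",
    "gmt": "genesets.gmt",
    "drugs": "drugs.csv",
    "methylation": "methylation.tsv",
    "truth": "truth.json",
}

_FLOAT = "%.10g"


@dataclass
class PipelineConfig:
    patient_counts: str
    cellline_fpkm: str
    gtf: str
    clinical: str
    gmt: str
    drugs: str
    out_dir: str
    patient_fpkm: str | None = None
    methylation: str | None = None
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    survival_rule: str = "median"
    gsea_q: float = 0.25
    n_perm: int = 200
    cis_window: int = 1_000_000
    k_rank: int = 4
    k_test: int = 6
    ratio_cutoff: float = 0.25
    hit_q: float = 0.10
    focal_gene: str | None = None
    seed: int = 0

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["thresholds"]["biotype_filter"] = sorted(d["thresholds"]["biotype_filter"])
        d["thresholds"]["exclude_classes"] = sorted(d["thresholds"]["exclude_classes"])
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        text = source if str(source).lstrip().startswith("{") else Path(source).read_text()
        d = json.loads(text)
        th = d.pop("thresholds", {})
        th["biotype_filter"] = frozenset(th.get("biotype_filter", ["lncRNA"]))
        th["exclude_classes"] = frozenset(th.get("exclude_classes", ["NL"]))
        return cls(thresholds=ScreenThresholds(**th), **d)

    @classmethod
    def from_data_dir(cls, data_dir, out_dir, **overrides) -> "PipelineConfig":
        data_dir = Path(data_dir)
        f = DEFAULT_FILENAMES
        methyl = data_dir / f["methylation"]
        return cls(
            patient_counts=str(data_dir / f["patient_counts"]),
            patient_fpkm=str(data_dir / f["patient_fpkm"]),
            cellline_fpkm=str(data_dir / f["cellline_fpkm"]),
            gtf=str(data_dir / f["gtf"]),
            clinical=str(data_dir / f["clinical"]),
            gmt=str(data_dir / f["gmt"]),
            drugs=str(data_dir / f["drugs"]),
            methylation=str(methyl) if methyl.exists() else None,
            out_dir=str(out_dir),
            **overrides,
        )


def simulate_to_dir(
    config: simdata.CohortConfig,
    out_dir,
    hazard_ratio: float = 3.0,
    censoring_rate: float = 0.2,
    n_compounds: int = 30,
    n_sensitive: int = 3,
    n_gene_sets: int = 10,
    n_probes: int = 30,
) -> simdata.SyntheticCohort:
    """Generate a full synthetic study and write every table as text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    f = DEFAULT_FILENAMES

    cohort = simdata.generate_cohort(config)
    truth = cohort.truth
    ann = cohort.annotation
    lengths = ann.lengths(cohort.patients.gene_ids)
    patient_fpkm = exprcore.fpkm(cohort.patients, lengths)
    cl_fpkm = exprcore.fpkm(cohort.cell_lines, lengths)

    io.write_expression_tsv(cohort.patients, out / f["patient_counts"])
    io.write_expression_tsv(patient_fpkm, out / f["patient_fpkm"])
    io.write_expression_tsv(cl_fpkm, out / f["cellline_fpkm"])
    io.write_gtf(ann, out / f["gtf"])

    focal = truth.planted_candidate_ids[0] if truth.planted_candidate_ids else None
    tumor = [
        s for s in cohort.patients.sample_ids
        if cohort.patients.sample_class[s] in ("BL", "HER2", "LA", "LB", "NL")
    ]
    if focal is not None:
        focal_expr = np.log2(patient_fpkm.values.loc[focal, tumor] + 1.0)
        surv = simdata.generate_survival(
            focal_expr, hazard_ratio, censoring_rate, seed=config.seed + 1
        )
        truth.planted_hazard_ratio = hazard_ratio
    else:
        surv = pd.DataFrame(columns=["time", "event", "group"])
    clin = pd.DataFrame(index=pd.Index(cohort.patients.sample_ids, name="sample_id"))
    clin["time_days"] = surv["time"].reindex(clin.index).fillna(0.0)
    clin["event"] = surv["event"].reindex(clin.index).fillna(0).astype(int)
    clin["class"] = cohort.patients.sample_class
    io.write_clinical(clin, out / f["clinical"])

    sets = simdata.generate_genesets(
        truth, ann, n_sets=n_gene_sets, set_size=max(len(truth.responsive_set_ids), 5),
        seed=config.seed + 2,
    )
    io.write_gmt(sets, out / f["gmt"])

    if focal is not None:
        line_expr = np.log2(cl_fpkm.values.loc[focal] + 1.0)
        drugs, slopes = simdata.generate_drug_response(
            line_expr, n_compounds=n_compounds, n_sensitive=n_sensitive, seed=config.seed + 3
        )
        truth.compound_slopes = slopes
        io.write_drug_csv(drugs, out / f["drugs"])

    betas = simdata.generate_methylation(
        cohort.patients.sample_class, hypo_class="BL", n_probes=n_probes, seed=config.seed + 4
    )
    truth.planted_hypomethylated_class = "BL"
    io.write_methylation_tsv(betas, out / f["methylation"])

    truth.to_json(out / f["truth"])
    return cohort


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON)."""
    cfg = config
    required = dict(
        patient_counts=cfg.patient_counts, cellline_fpkm=cfg.cellline_fpkm, gtf=cfg.gtf,
        clinical=cfg.clinical, gmt=cfg.gmt, drugs=cfg.drugs,
    )
    for name, p in {**required, "patient_fpkm": cfg.patient_fpkm, "methylation": cfg.methylation}.items():
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input {name!r} not found: {p}")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # annotate the failing stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # ---- load -------------------------------------------------------------
    clinical = io.read_clinical(cfg.clinical)
    classes = clinical["class"]
    counts = io.read_expression_tsv(cfg.patient_counts)
    if (counts.sample_class == "UNKNOWN").all():
        counts = ExpressionMatrix(counts.values, classes, counts.unit)
    annotation = io.read_gtf(cfg.gtf)
    if cfg.patient_fpkm:
        fpkm = io.read_expression_tsv(cfg.patient_fpkm, sample_class=counts.sample_class, unit="fpkm")
    else:
        fpkm = exprcore.fpkm(counts, annotation.lengths(counts.gene_ids))
    cl_fpkm = io.read_expression_tsv(cfg.cellline_fpkm)
    gene_sets = io.read_gmt(cfg.gmt)
    drugs = io.read_drug_csv(cfg.drugs)

    # ---- screen -----------------------------------------------------------
    def do_screen():
        table = run_candidate_screen(counts, fpkm, cl_fpkm, annotation, cfg.thresholds)
        rec = table.records.copy()
        rec.to_csv(out / "candidates.tsv", sep="\t", float_format=_FLOAT)
        return table

    table = _stage("screen", do_screen)
    outputs["candidates.tsv"] = _sha256(out / "candidates.tsv")
    passing = table.passing_ids
    focal = cfg.focal_gene or (passing[0] if passing else None)

    tumor_samples = [
        s for s in fpkm.sample_ids
        if classes.get(s) in ("BL", "HER2", "LA", "LB") and s in clinical.index
    ]

    # ---- survival per candidate --------------------------------------------
    def do_survival():
        rows = []
        for gid in passing:
            expr = fpkm.values.loc[gid, tumor_samples]
            groups = survival.dichotomize(expr, cfg.survival_rule)
            assigned = groups.dropna().index
            tbl = pd.DataFrame(
                {
                    "time": clinical.loc[assigned, "time_days"],
                    "event": clinical.loc[assigned, "event"],
                    "group": groups.loc[assigned],
                }
            )
            res = survival.logrank_test(tbl)
            rows.append(
                (gid, int((groups == "high").sum()), int((groups == "low").sum()),
                 res.chi_square, res.p_value)
            )
        df = pd.DataFrame(rows, columns=["gene_id", "n_high", "n_low", "chi_square", "p_value"])
        if len(df):
            df["bh_q"] = survival.bh_adjust(df["p_value"])
        else:
            df["bh_q"] = []
        df.set_index("gene_id").to_csv(out / "survival.tsv", sep="\t", float_format=_FLOAT)
        if focal is not None:
            expr = fpkm.values.loc[focal, tumor_samples]
            groups = survival.dichotomize(expr, cfg.survival_rule)
            km_rows = []
            for label in ("high", "low"):
                members = groups.index[groups == label]
                km = survival.km_curve(
                    clinical.loc[members, "time_days"], clinical.loc[members, "event"]
                )
                km.insert(0, "group", label)
                km_rows.append(km)
            pd.concat(km_rows, ignore_index=True).to_csv(
                out / "survival_km.tsv", sep="\t", index=False, float_format=_FLOAT
            )

    _stage("survival", do_survival)
    outputs["survival.tsv"] = _sha256(out / "survival.tsv")
    if (out / "survival_km.tsv").exists():
        outputs["survival_km.tsv"] = _sha256(out / "survival_km.tsv")

    # ---- enrichment -----------------------------------------------------------
    def do_gsea():
        if focal is None:
            pd.DataFrame(columns=["size", "es", "nes", "p_perm", "fdr_q", "leading_edge"]).to_csv(
                out / "gsea.tsv", sep="\t"
            )
            return
        target_samples = [s for s in fpkm.sample_ids if classes.get(s) == cfg.thresholds.target_class]
        log_fpkm = np.log2(fpkm.values[target_samples] + 1.0)
        high, low = enrich.quartile_contrast(log_fpkm.loc[focal], cfg.gsea_q)
        usable = {
            name: [g for g in members if g in log_fpkm.index]
            for name, members in gene_sets.items()
        }
        usable = {k: v for k, v in usable.items() if 0 < len(v) < len(log_fpkm.index)}
        res = enrich.permutation_significance(
            log_fpkm, (high, low), usable, n_perm=cfg.n_perm, mode="phenotype", seed=cfg.seed
        )
        res.to_csv(out / "gsea.tsv", sep="\t", float_format=_FLOAT)

    _stage("gsea", do_gsea)
    outputs["gsea.tsv"] = _sha256(out / "gsea.tsv")

    # ---- cis ----------------------------------------------------------------
    def do_cis():
        if focal is None:
            pd.DataFrame(columns=["r", "p_value"]).to_csv(out / "cis.tsv", sep="\t")
            return
        nbrs = cisreg.find_neighbors(annotation, focal, cfg.cis_window)
        corr = cisreg.neighbor_correlation(fpkm, focal, nbrs)
        ann = annotation.table.loc[corr.index, ["chrom", "start", "end", "biotype"]]
        pd.concat([ann, corr], axis=1).to_csv(out / "cis.tsv", sep="\t", float_format=_FLOAT)
        if cfg.methylation:
            betas = io.read_methylation_tsv(cfg.methylation)
            target = [s for s in betas.columns if classes.get(s) == cfg.thresholds.target_class]
            rest = [
                s for s in betas.columns
                if classes.get(s) in ("HER2", "LA", "LB", "NORMAL")
            ]
            res = cisreg.methylation_compare(betas, target, rest)
            res["group_a"] = cfg.thresholds.target_class
            res["group_b"] = "other"
            Path(out / "cis_methylation.json").write_text(
                json.dumps(res, indent=2, sort_keys=True) + "\n"
            )

    _stage("cis", do_cis)
    outputs["cis.tsv"] = _sha256(out / "cis.tsv")
    if (out / "cis_methylation.json").exists():
        outputs["cis_methylation.json"] = _sha256(out / "cis_methylation.json")

    # ---- drug screen -----------------------------------------------------------
    def do_drugs():
        if focal is None or focal not in cl_fpkm.gene_ids:
            pd.DataFrame(columns=["ic50_ratio", "pearson_r", "pearson_p", "bh_q", "hit"]).to_csv(
                out / "drugscreen.tsv", sep="\t"
            )
            return
        lines = [l for l in cl_fpkm.sample_ids if l in set(drugs["cell_line"])]
        expr = np.log2(cl_fpkm.values.loc[focal, lines] + 1.0)
        res = drugscreen.run_drug_screen(
            expr, drugs, k_rank=cfg.k_rank, k_test=cfg.k_test,
            ratio_cutoff=cfg.ratio_cutoff, hit_q=cfg.hit_q,
        )
        res.to_csv(out / "drugscreen.tsv", sep="\t", float_format=_FLOAT)

    _stage("drugscreen", do_drugs)
    outputs["drugscreen.tsv"] = _sha256(out / "drugscreen.tsv")

    manifest = {
        "package": "lncscout",
        "version": __version__,
        "seed": cfg.seed,
        "focal_gene": focal,
        "n_passing_candidates": len(passing),
        "passing_candidates": list(passing),
        "config": json.loads(cfg.to_json()),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
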