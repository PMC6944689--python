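"""Synthetic breast-cancer cohort generator with planted ground truth.

Emulates the data structure of a TCGA-style bulk RNA-seq cohort across six
sample classes (BL, HER2, LA, LB, NL, NORMAL): negative-binomial counts,
log-normal library depths, gene lengths, and a set of *planted* effects with a
machine-readable truth ledger:

* basal-restricted lncRNA candidates, expressed at high fold-change in a fixed
  fraction of BL patients ("expressors");
* decoy genes, each engineered to violate exactly one screen filter;
* a protein-coding neighbor 13 kb downstream of the first planted (focal)
  lncRNA, co-expressed with it at a configurable target correlation;
* a module of "responsive" genes coupled to the focal gene's expressor status
  (the substrate for gene-set enrichment);
* survival times whose hazard depends on focal expression, promoter
  methylation hypomethylated in one class, and compounds whose log-IC50 falls
  with a biomarker's expression.

Expressor status per (gene, class) is assigned to an exact number of samples,
round(fraction * n_class), drawn without replacement; this pins each planted
gene's within-class prevalence at its nominal value so that recovery
experiments measure the screen, not binomial noise in the truth.

All randomness flows from one root seed through named substreams, so
regenerating any single table is reproducible in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import ExpressionMatrix, GeneAnnotation, SAMPLE_CLASSES

__all__ = [
    "CohortConfig",
    "TruthLedger",
    "SyntheticCohort",
    "generate_cohort",
    "generate_survival",
    "generate_drug_response",
    "generate_methylation",
    "generate_genesets",
    "desk_config",
    "full_config",
    "demo_config",
]

TUMOR_SUBTYPES = ("BL", "HER2", "LA", "LB")  # NL handled separately

# FPKM-scale baseline of planted lncRNAs; expressors reach base * planted_fc.
PLANTED_BASE_FPKM = 0.2
# FPKM level planted genes reach in their expressing cell lines.
CELLLINE_EXPR_FPKM = 4.0
RESPONSIVE_BASE_FPKM = 10.0
NEIGHBOR_BASE_FPKM = 8.0
NEIGHBOR_GAP_BP = 13_000
GENE_GAP_BP = 2_500_000


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from the root seed and a stream name."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"BL": 40, "HER2": 20, "LA": 80, "LB": 40, "NL": 10, "NORMAL": 20}
    )
    n_genes: int = 2000
    n_planted: int = 9
    n_decoys: int = 10
    expressor_fraction_bl: float = 0.40
    expressor_fraction_other: float = 0.05
    planted_fc: float = 20.0
    dispersion: float = 5.0  # NB size parameter; smaller = more overdispersed
    libsize_log_mean: float = float(np.log(1e7))
    libsize_log_sd: float = 0.25
    n_responsive: int = 25
    responsive_fc: float = 3.0
    neighbor_target_corr: float = 0.9
    n_celllines_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"BL": 8, "HER2": 4, "LA": 6, "LB": 4}
    )
    n_expressing_celllines: int = 4
    lncrna_fraction_background: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_per_class.items():
            if cls not in SAMPLE_CLASSES:
                raise ValueError(f"unknown sample class {cls!r}")
            if n < 0:
                raise ValueError("class sizes must be >= 0")
        for frac in (self.expressor_fraction_bl, self.expressor_fraction_other):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("expressor fractions must be in [0, 1]")
        if self.planted_fc <= 0:
            raise ValueError("planted_fc must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion (NB size) must be positive")
        n_special = self.n_planted + self.n_decoys + self.n_responsive + 1
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted exceeds n_genes")
        if n_special > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {self.n_planted} planted + "
                f"{self.n_decoys} decoys + {self.n_responsive} responsive + 1 neighbor"
            )


def desk_config(seed: int = 0, **overrides) -> CohortConfig:
    """Desk-scale preset: 180 tumor patients + 10 NL + 20 normals, 2000 genes."""
    return CohortConfig(seed=seed, **overrides)


def full_config(seed: int = 0, **overrides) -> CohortConfig:
    """Full-scale preset mirroring the 131/64/404/170 tumor subtype split."""
    params = dict(
        n_per_class={"BL": 131, "HER2": 64, "LA": 404, "LB": 170, "NL": 25, "NORMAL": 113},
        n_genes=2000,
    )
    params.update(overrides)
    return CohortConfig(seed=seed, **params)


def demo_config(seed: int = 0, **overrides) -> CohortConfig:
    """Small preset used by the bundled end-to-end demo and golden tests."""
    params = dict(
        n_per_class={"BL": 24, "HER2": 8, "LA": 24, "LB": 12, "NL": 4, "NORMAL": 12},
        n_genes=250,
        n_planted=3,
        n_decoys=7,
        n_responsive=15,
        n_celllines_per_class={"BL": 6, "HER2": 2, "LA": 3, "LB": 2},
    )
    params.update(overrides)
    return CohortConfig(seed=seed, **params)


@dataclass
class TruthLedger:
    """Ground truth of every planted effect, serializable to JSON."""

    planted_candidate_ids: list = field(default_factory=list)
    # gene id -> {"base_fpkm": .., "fold_change": .., "expressor_fraction": {class: frac}}
    planted_profiles: dict = field(default_factory=dict)
    # decoy gene id -> name of the single screen flag it is designed to violate
    decoy_violations: dict = field(default_factory=dict)
    planted_neighbor_pair: tuple | None = None  # (focal id, neighbor id, target corr)
    responsive_set_ids: list = field(default_factory=list)
    responsive_set_name: str | None = None
    focal_expressor_samples: list = field(default_factory=list)
    planted_hazard_ratio: float | None = None
    # compound -> slope of log10 IC50 on standardized expression (0 for nulls)
    compound_slopes: dict = field(default_factory=dict)
    planted_hypomethylated_class: str | None = None

    @property
    def planted_sensitive_compounds(self) -> list:
        return [c for c, s in self.compound_slopes.items() if s != 0.0]

    def to_json(self, path=None) -> str:
        d = asdict(self)
        if d["planted_neighbor_pair"] is not None:
            d["planted_neighbor_pair"] = list(d["planted_neighbor_pair"])
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "TruthLedger":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        if d.get("planted_neighbor_pair") is not None:
            d["planted_neighbor_pair"] = tuple(d["planted_neighbor_pair"])
        return cls(**d)


@dataclass
class _PlantSpec:
    """Internal recipe for one planted or decoy gene."""

    gene_id: str
    biotype: str = "lncRNA"
    base_fpkm: float = PLANTED_BASE_FPKM
    length_bp: int | None = None  # None -> drawn in [2000, 20000]
    # class -> (exact number of expressor samples, per-expressor fold multiplier)
    class_expressors: dict = field(default_factory=dict)
    n_expressing_lines: int = 4
    violated: str | None = None


@dataclass
class SyntheticCohort:
    patients: ExpressionMatrix  # counts
    cell_lines: ExpressionMatrix  # counts
    annotation: GeneAnnotation
    truth: TruthLedger
    config: CohortConfig


def _planted_spec(cfg: CohortConfig, gene_id: str) -> _PlantSpec:
    expr = {"BL": (int(round(cfg.expressor_fraction_bl * cfg.n_per_class.get("BL", 0))), cfg.planted_fc)}
    for cls in ("HER2", "LA", "LB", "NL"):
        n = cfg.n_per_class.get(cls, 0)
        expr[cls] = (int(round(cfg.expressor_fraction_other * n)), cfg.planted_fc)
    return _PlantSpec(gene_id, class_expressors=expr, n_expressing_lines=cfg.n_expressing_celllines)


def _decoy_specs(cfg: CohortConfig) -> list[_PlantSpec]:
    """One decoy per screen filter, cycled to fill ``n_decoys``.

    Each decoy reproduces the planted profile except for a single engineered
    violation, with effect sizes chosen far from every other filter boundary so
    that only the designed flag fails.
    """
    n = cfg.n_per_class

    def kind_biotype(gid):
        s = _planted_spec(cfg, gid)
        s.biotype = "protein_coding"
        s.violated = "biotype"
        return s

    def kind_fc_normal(gid):
        s = _planted_spec(cfg, gid)
        s.class_expressors["NORMAL"] = (
            int(round(cfg.expressor_fraction_bl * n.get("NORMAL", 0))),
            cfg.planted_fc,
        )
        s.violated = "fc_vs_normal"
        return s

    def kind_fc_other(gid):
        # LA expressed in exactly 10% of samples at a large per-expressor fold:
        # mean matches BL (FC < 1.5 fails) while LA prevalence stays at 0.10.
        s = _planted_spec(cfg, gid)
        s.class_expressors["LA"] = (int(round(0.10 * n.get("LA", 0))), 6.0 * cfg.planted_fc)
        s.violated = "fc_vs_other_subtypes"
        return s

    def kind_base_mean(gid):
        # Short, near-silent gene whose BL expressors reach FPKM ~2 at tiny
        # absolute counts: passes prevalence and fold-change, fails baseMean.
        s = _planted_spec(cfg, gid)
        s.base_fpkm = 0.005
        s.length_bp = 200
        s.class_expressors = {"BL": (int(round(cfg.expressor_fraction_bl * n.get("BL", 0))), 400.0)}
        s.violated = "base_mean"
        return s

    def kind_prevalence(gid):
        # Expressed in only 5% of BL patients, at a fold large enough that the
        # BL mean still clears every fold-change filter.
        s = _planted_spec(cfg, gid)
        s.class_expressors = {"BL": (int(round(0.05 * n.get("BL", 0))), 7.5 * cfg.planted_fc)}
        s.violated = "target_prevalence"
        return s

    def kind_other_prevalence(gid):
        # Expressed in 25% of LA patients at a modest fold: LA prevalence trips
        # the <15% cut while the BL/LA mean ratio stays above 1.5.
        s = _planted_spec(cfg, gid)
        s.class_expressors["LA"] = (int(round(0.25 * n.get("LA", 0))), cfg.planted_fc / 2.0)
        s.violated = "other_prevalence"
        return s

    def kind_celllines(gid):
        s = _planted_spec(cfg, gid)
        s.n_expressing_lines = 1
        s.violated = "cell_lines"
        return s

    kinds = [
        kind_biotype,
        kind_fc_normal,
        kind_fc_other,
        kind_base_mean,
        kind_prevalence,
        kind_other_prevalence,
        kind_celllines,
    ]
    specs = []
    for i in range(cfg.n_decoys):
        make = kinds[i % len(kinds)]
        specs.append(make(f"DECOY{i + 1:02d}"))
    return specs


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, size: float) -> np.ndarray:
    """Negative binomial draws, mean ``mu``, size (dispersion) parameter ``size``."""
    mu = np.asarray(mu, dtype=float)
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _assign_expressors(rng, samples_by_class: dict, spec: _PlantSpec) -> list:
    chosen = []
    for cls, (n_expr, _fc) in spec.class_expressors.items():
        pool = samples_by_class.get(cls, [])
        k = min(int(n_expr), len(pool))
        if k > 0:
            chosen.extend(rng.choice(pool, size=k, replace=False))
    return sorted(chosen)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate patient and cell-line count matrices, annotation and truth.

    Counts_gs ~ NB(mean = x_g * m_gs * length_g * depth_s / 1e9, size =
    dispersion) where x_g is the gene's FPKM-scale expression level, m_gs the
    planted multiplier (``planted_fc`` for expressor samples, 1 otherwise) and
    depth_s a log-normal library depth. Background levels are rescaled so that
    sum_g x_g * length_g / 1e9 = 1, which makes column-sum FPKM recover x_g.
    """
    cfg = config
    truth = TruthLedger()

    # ---- gene catalogue ---------------------------------------------------
    rng_genes = _substream(cfg.seed, "genes")
    planted = [_planted_spec(cfg, f"PLANTED{i + 1:02d}") for i in range(cfg.n_planted)]
    decoys = _decoy_specs(cfg)
    specials = planted + decoys
    n_background = cfg.n_genes - len(specials) - cfg.n_responsive - 1
    bg_ids = [f"BG{i + 1:05d}" for i in range(n_background)]
    resp_ids = [f"RESP{i + 1:03d}" for i in range(cfg.n_responsive)]
    neighbor_id = "NEIGHBOR01"
    focal_id = planted[0].gene_id if planted else None

    lengths = {}
    for gid in bg_ids:
        lengths[gid] = int(rng_genes.integers(200, 20001))
    for gid in resp_ids:
        lengths[gid] = int(rng_genes.integers(2000, 20001))
    for spec in specials:
        lengths[spec.gene_id] = (
            spec.length_bp if spec.length_bp is not None else int(rng_genes.integers(2000, 20001))
        )
    lengths[neighbor_id] = int(rng_genes.integers(2000, 20001))

    # FPKM-scale baseline expression levels
    x = {}
    bg_x = rng_genes.lognormal(mean=np.log(16.0), sigma=1.5, size=n_background)
    for gid, val in zip(bg_ids, bg_x):
        x[gid] = float(val)
    for gid in resp_ids:
        x[gid] = RESPONSIVE_BASE_FPKM
    for spec in specials:
        x[spec.gene_id] = spec.base_fpkm
    x[neighbor_id] = NEIGHBOR_BASE_FPKM

    # rescale background so total x*len/1e9 == 1 (FPKM scale calibration)
    special_mass = sum(x[g] * lengths[g] for g in x if g not in bg_ids) / 1e9
    bg_mass = sum(x[g] * lengths[g] for g in bg_ids) / 1e9
    if bg_mass > 0:
        scale = max(1.0 - special_mass, 0.05) / bg_mass
        for gid in bg_ids:
            x[gid] *= scale

    bg_biotype = np.where(
        rng_genes.random(n_background) < cfg.lncrna_fraction_background, "lncRNA", "protein_coding"
    )

    gene_order = bg_ids + resp_ids + [s.gene_id for s in specials] + [neighbor_id]

    # ---- samples ------------------------------------------------------------
    samples, classes = [], []
    for cls in SAMPLE_CLASSES:
        for i in range(cfg.n_per_class.get(cls, 0)):
            samples.append(f"{cls}_{i + 1:03d}")
            classes.append(cls)
    sample_class = pd.Series(classes, index=samples, name="class")
    samples_by_class = {cls: [s for s, c in zip(samples, classes) if c == cls] for cls in SAMPLE_CLASSES}

    # ---- planted multipliers ------------------------------------------------
    rng_plant = _substream(cfg.seed, "expressors")
    n_s = len(samples)
    sample_pos = {s: i for i, s in enumerate(samples)}
    mult = pd.DataFrame(1.0, index=gene_order, columns=samples)
    expressors_of = {}
    for spec in specials:
        chosen = _assign_expressors(rng_plant, samples_by_class, spec)
        expressors_of[spec.gene_id] = chosen
        for cls, (n_expr, fc) in spec.class_expressors.items():
            members = [s for s in chosen if sample_class[s] == cls]
            if members:
                mult.loc[spec.gene_id, members] = fc

    focal_expressors = expressors_of.get(focal_id, [])
    for gid in resp_ids:
        if focal_expressors:
            mult.loc[gid, focal_expressors] = cfg.responsive_fc

    # ---- counts -------------------------------------------------------------
    rng_depth = _substream(cfg.seed, "depth")
    depth = rng_depth.lognormal(cfg.libsize_log_mean, cfg.libsize_log_sd, size=n_s)
    len_vec = np.array([lengths[g] for g in gene_order], dtype=float)
    x_vec = np.array([x[g] for g in gene_order], dtype=float)
    mu = (x_vec * len_vec / 1e9)[:, None] * mult.to_numpy() * depth[None, :]

    rng_counts = _substream(cfg.seed, "counts")
    counts = _nb_counts(rng_counts, mu, cfg.dispersion).astype(np.int64)
    counts = pd.DataFrame(counts, index=gene_order, columns=samples)

    # ---- co-expressed neighbor (Gaussian copula on the focal gene) ----------
    if focal_id is not None:
        rng_nbr = _substream(cfg.seed, "neighbor")
        focal_fpkm = counts.loc[focal_id].to_numpy() * 1e9 / (lengths[focal_id] * depth)
        u = np.log2(focal_fpkm + 1.0)
        s_u = u.std()
        z = (u - u.mean()) / s_u if s_u > 0 else np.zeros(n_s)
        rho = float(np.clip(cfg.neighbor_target_corr, -1.0, 1.0))
        w = rho * z + np.sqrt(max(1.0 - rho**2, 0.0)) * rng_nbr.standard_normal(n_s)
        nbr_fpkm = NEIGHBOR_BASE_FPKM * 2.0 ** (0.7 * w)
        nbr_mu = nbr_fpkm * lengths[neighbor_id] * depth / 1e9
        counts.loc[neighbor_id] = rng_nbr.poisson(nbr_mu).astype(np.int64)

    patients = ExpressionMatrix(counts, sample_class, unit="counts")

    # ---- cell lines ----------------------------------------------------------
    lines, line_classes = [], []
    for cls in ("BL", "HER2", "LA", "LB"):
        for i in range(cfg.n_celllines_per_class.get(cls, 0)):
            lines.append(f"CL_{cls}_{i + 1:02d}")
            line_classes.append(cls)
    line_class = pd.Series(line_classes, index=lines, name="class")
    bl_lines = [l for l, c in zip(lines, line_classes) if c == "BL"]

    rng_cl = _substream(cfg.seed, "celllines")
    cl_mult = pd.DataFrame(1.0, index=gene_order, columns=lines)
    expressing_lines = {}
    for spec in specials:
        k = min(spec.n_expressing_lines, len(bl_lines))
        chosen = sorted(rng_cl.choice(bl_lines, size=k, replace=False)) if k else []
        expressing_lines[spec.gene_id] = chosen
        if chosen:
            # per-line fold chosen to reach a fixed FPKM in expressing lines
            cl_mult.loc[spec.gene_id, chosen] = CELLLINE_EXPR_FPKM / spec.base_fpkm
    focal_lines = expressing_lines.get(focal_id, [])
    for gid in resp_ids:
        if focal_lines:
            cl_mult.loc[gid, focal_lines] = cfg.responsive_fc
    if focal_id is not None and focal_lines:
        cl_mult.loc[neighbor_id, focal_lines] = 4.0  # neighbor co-expressed in lines too

    cl_depth = rng_cl.lognormal(cfg.libsize_log_mean, cfg.libsize_log_sd, size=len(lines))
    cl_mu = (x_vec * len_vec / 1e9)[:, None] * cl_mult.to_numpy() * cl_depth[None, :]
    cl_counts = pd.DataFrame(
        _nb_counts(rng_cl, cl_mu, cfg.dispersion).astype(np.int64), index=gene_order, columns=lines
    )
    cell_lines = ExpressionMatrix(cl_counts, line_class, unit="counts")

    # ---- annotation -----------------------------------------------------------
    layout = [g for g in gene_order if g != neighbor_id]
    if focal_id is not None:
        layout.insert(layout.index(focal_id) + 1, neighbor_id)
    else:
        layout.append(neighbor_id)
    n_chrom = 22
    per_chrom = int(np.ceil(len(layout) / n_chrom))
    rows = []
    biotype_of = {gid: bt for gid, bt in zip(bg_ids, bg_biotype)}
    biotype_of.update({gid: "protein_coding" for gid in resp_ids})
    biotype_of.update({s.gene_id: s.biotype for s in specials})
    biotype_of[neighbor_id] = "protein_coding"
    pos = 10_000
    prev_chrom = None
    prev_end = None
    for i, gid in enumerate(layout):
        chrom = f"chr{i // per_chrom + 1}"
        if gid == neighbor_id and prev_chrom is not None:
            # pin the neighbor 13 kb downstream of the focal gene's end
            chrom = prev_chrom
            start = prev_end + NEIGHBOR_GAP_BP
        else:
            if chrom != prev_chrom:
                pos = 10_000
            start = pos
        prev_chrom = chrom
        end = start + lengths[gid]
        prev_end = end
        rows.append(
            dict(
                gene_id=gid,
                gene_name=gid,
                biotype=biotype_of[gid],
                chrom=chrom,
                start=start,
                end=end,
                strand="+",
                length_bp=lengths[gid],
            )
        )
        pos = end + GENE_GAP_BP
    ann_table = pd.DataFrame(rows).set_index("gene_id")
    annotation = GeneAnnotation(ann_table)

    # ---- truth -----------------------------------------------------------------
    truth.planted_candidate_ids = [s.gene_id for s in planted]
    for spec in specials:
        fracs = {
            cls: (n_expr / cfg.n_per_class[cls] if cfg.n_per_class.get(cls, 0) else 0.0)
            for cls, (n_expr, _fc) in spec.class_expressors.items()
        }
        truth.planted_profiles[spec.gene_id] = {
            "base_fpkm": spec.base_fpkm,
            "fold_change": {cls: fc for cls, (_n, fc) in spec.class_expressors.items()},
            "expressor_fraction": fracs,
            "n_expressing_cell_lines": len(expressing_lines.get(spec.gene_id, [])),
        }
    truth.decoy_violations = {s.gene_id: s.violated for s in decoys}
    if focal_id is not None:
        truth.planted_neighbor_pair = (focal_id, neighbor_id, cfg.neighbor_target_corr)
        truth.focal_expressor_samples = list(focal_expressors)
    truth.responsive_set_ids = list(resp_ids)

    return SyntheticCohort(patients, cell_lines, annotation, truth, cfg)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def generate_survival(
    expression: pd.Series,
    hazard_ratio: float,
    censoring_rate: float = 0.2,
    seed: int = 0,
    baseline_hazard: float = 1.0 / 1000.0,
) -> pd.DataFrame:
    """Exponential survival with hazard h0 * HR^{I(high expression)}.

    The high group is the samples strictly above the median of ``expression``.
    Censoring times are uniform on (0, c) with c solved so that the expected
    censored fraction equals ``censoring_rate`` (exactly under HR = 1; via the
    group mixture otherwise). Returns columns sample_id (index), time, event,
    group.
    """
    expression = pd.Series(expression)
    if len(expression) == 0:
        raise ValueError("empty expression vector")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0.0 <= censoring_rate < 1.0:
        raise ValueError("censoring_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    high = (expression > expression.median()).to_numpy()
    hazards = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    times_true = rng.exponential(1.0 / hazards)

    if censoring_rate == 0.0:
        time, event = times_true, np.ones(len(expression), dtype=int)
    else:
        hs, weights = np.unique(hazards, return_counts=True)
        weights = weights / weights.sum()

        def censored_frac(c):
            # P(C < T) with C ~ U(0, c), T ~ Exp(h): (1 - exp(-h c)) / (h c)
            return float(np.sum(weights * (1.0 - np.exp(-hs * c)) / (hs * c))) - censoring_rate

        lo, hi = 1e-9 / baseline_hazard, 1e9 / baseline_hazard
        c = optimize.brentq(censored_frac, lo, hi)
        cens = rng.uniform(0.0, c, size=len(expression))
        event = (times_true <= cens).astype(int)
        time = np.minimum(times_true, cens)

    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "group": np.where(high, "high", "low"),
        },
        index=expression.index.rename("sample_id"),
    )


# ---------------------------------------------------------------------------
# drug response
# ---------------------------------------------------------------------------

def generate_drug_response(
    expression: pd.Series,
    n_compounds: int = 30,
    n_sensitive: int = 3,
    slope: float = -0.5,
    noise_sd: float = 0.375,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-(cell line, compound) IC50 table with planted sensitive compounds.

    log10 IC50 = a_c + slope * z(expression) + eps for sensitive compounds and
    a_c + eps otherwise, with eps ~ N(0, noise_sd). The default slope/noise pair
    gives the planted compounds a population expression-IC50 correlation of
    slope / sqrt(slope^2 + noise_sd^2) = -0.8. Returns the long-format table
    (cell_line, compound, ic50_uM) and a {compound: slope} truth map (exactly 0
    for null compounds).
    """
    expression = pd.Series(expression)
    if len(expression) < 3:
        raise ValueError("need at least 3 cell lines")
    if n_sensitive > n_compounds:
        raise ValueError("n_sensitive exceeds n_compounds")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    vals = expression.to_numpy(dtype=float)
    sd = vals.std()
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros(len(vals))

    names = [f"compound_{i + 1:02d}" for i in range(n_compounds)]
    sensitive = set(rng.choice(names, size=n_sensitive, replace=False)) if n_sensitive else set()
    rows, slopes = [], {}
    for name in names:
        a = rng.uniform(-0.5, 1.5)
        s = slope if name in sensitive else 0.0
        slopes[name] = float(s)
        log_ic50 = a + s * z + rng.normal(0.0, noise_sd, size=len(z))
        for line, v in zip(expression.index, log_ic50):
            rows.append((line, name, float(10.0**v)))
    table = pd.DataFrame(rows, columns=["cell_line", "compound", "ic50_uM"])
    return table, slopes


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def generate_methylation(
    classes: pd.Series,
    hypo_class: str,
    n_probes: int = 30,
    seed: int = 0,
    mean_other: float = 0.55,
    effect: float = 0.30,
    concentration: float = 10.0,
) -> pd.DataFrame:
    """Beta-distributed promoter CpG beta values, lower mean in ``hypo_class``.

    Probe x sample matrix; samples of ``hypo_class`` have mean beta
    ``mean_other - effect`` (``effect = 0`` gives the null). Means are
    parameterized as Beta(m*conc, (1-m)*conc).
    """
    classes = pd.Series(classes)
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if hypo_class not in set(classes):
        raise ValueError(f"unknown hypo_class {hypo_class!r}")
    mean_hypo = mean_other - effect
    if not (0.0 < mean_hypo < 1.0 and 0.0 < mean_other < 1.0):
        raise ValueError("beta means must fall in (0, 1)")
    rng = np.random.default_rng(seed)
    means = np.where(classes.to_numpy() == hypo_class, mean_hypo, mean_other)
    a = means * concentration
    b = (1.0 - means) * concentration
    betas = rng.beta(a[None, :], b[None, :], size=(n_probes, len(classes)))
    probes = [f"cg{i + 1:05d}" for i in range(n_probes)]
    return pd.DataFrame(betas, index=probes, columns=classes.index)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def generate_genesets(
    truth: TruthLedger,
    annotation: GeneAnnotation,
    n_sets: int = 10,
    set_size: int = 25,
    seed: int = 0,
) -> dict[str, list]:
    """Gene sets for enrichment: one responsive set plus random sets.

    The responsive set is the planted module whose expression is coupled to the
    focal gene's expressor status; the rest are uniform draws from the genes
    with no planted coupling (responsive module, candidates and the focal
    neighbor excluded, so random sets are genuinely null; they may overlap one
    another). Records the responsive set's name in ``truth``.
    """
    universe = list(annotation.gene_ids)
    coupled = set(truth.responsive_set_ids) | set(truth.planted_candidate_ids)
    if truth.planted_neighbor_pair is not None:
        coupled |= set(truth.planted_neighbor_pair[:2])
    null_pool = [g for g in universe if g not in coupled]
    if set_size >= len(universe):
        raise ValueError("set_size must be smaller than the gene universe")
    if set_size > len(null_pool):
        raise ValueError("set_size exceeds the uncoupled gene pool")
    rng = np.random.default_rng(seed)
    sets: dict[str, list] = {}
    resp = [g for g in truth.responsive_set_ids if g in annotation]
    if resp:
        sets["GS_RESPONSIVE"] = sorted(resp)[: max(set_size, 1)] if len(resp) > set_size else sorted(resp)
        truth.responsive_set_name = "GS_RESPONSIVE"
    n_random = n_sets - len(sets)
    for i in range(max(n_random, 0)):
        members = sorted(rng.choice(null_pool, size=set_size, replace=False))
        sets[f"GS_RANDOM{i + 1:02d}"] = list(members)
    return sets
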