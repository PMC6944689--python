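"""Gene-set enrichment: expressor contrast, weighted running-sum statistic,
permutation null with NES/FDR, and rank-based subtype enrichment of one gene.

The enrichment statistic is the weighted Kolmogorov-Smirnov running sum: walking
down a ranked gene list, hits increment by |metric|^p normalized to the set
total and misses decrement by 1/(N-k); the enrichment score (ES) is the signed
maximum deviation. Significance comes from phenotype (label shuffling) or
gene-set (random membership) permutations:

    p   = (1 + #{same-sign permuted |ES| >= |ES_obs|}) / (1 + #same-sign perms)
    NES = ES / mean(|same-sign permuted ES|)
    FDR = pooled same-sign null NES comparison (classic procedure)

Ranking ties are broken by gene id, so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "quartile_contrast",
    "signal_to_noise",
    "rank_genes",
    "enrichment_score",
    "permutation_significance",
    "subtype_enrichment",
]


def _values(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else pd.DataFrame(matrix)


def quartile_contrast(expression: pd.Series, q: float = 0.25) -> tuple[list, list]:
    """Top-q and bottom-q sample sets by a focal gene's expression.

    Both groups have floor(n*q) samples; ties are broken by sample id.
    """
    if not 0.0 < q < 0.5:
        raise ValueError("q must lie strictly between 0 and 0.5")
    expression = pd.Series(expression)
    k = int(np.floor(len(expression) * q))
    if k < 1:
        raise ValueError("not enough samples for non-empty quantile groups")
    by_high = sorted(expression.index, key=lambda s: (-expression[s], str(s)))
    by_low = sorted(expression.index, key=lambda s: (expression[s], str(s)))
    return list(by_high[:k]), list(by_low[:k])


def signal_to_noise(matrix, group_a, group_b) -> pd.Series:
    """Per-gene signal-to-noise ranking metric (mu_a - mu_b)/(sd_a + sd_b).

    Each group's standard deviation is floored at max(0.2*|mean|, 0.2), the
    convention that keeps low-variance genes from dominating the ranking.
    """
    group_a, group_b = list(group_a), list(group_b)
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("signal_to_noise needs at least 2 samples per group")
    v = _values(matrix)
    a, b = v[group_a], v[group_b]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum(a.std(axis=1, ddof=1), np.maximum(0.2 * mu_a.abs(), 0.2))
    sd_b = np.maximum(b.std(axis=1, ddof=1), np.maximum(0.2 * mu_b.abs(), 0.2))
    return ((mu_a - mu_b) / (sd_a + sd_b)).rename("signal_to_noise")


def rank_genes(metric: pd.Series) -> pd.Series:
    """Metric sorted by decreasing value, ties broken by gene id."""
    metric = pd.Series(metric)
    order = sorted(metric.index, key=lambda g: (-metric[g], str(g)))
    return metric.loc[order]


def _es_core(metric_sorted: np.ndarray, hit: np.ndarray, weight_p: float) -> tuple[float, np.ndarray]:
    n = len(metric_sorted)
    k = int(hit.sum())
    if k == 0 or k == n:
        raise ValueError("gene set must be a proper non-empty subset of the universe")
    w = np.where(hit, np.abs(metric_sorted) ** weight_p, 0.0)
    total = w.sum()
    if total == 0:  # all hit metrics are zero; fall back to unweighted steps
        w = hit.astype(float)
        total = float(k)
    running = np.cumsum(w / total - (~hit) / (n - k))
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def enrichment_score(ranked: pd.Series, gene_set, weight_p: float = 1.0):
    """ES, running-sum profile and leading edge for one gene set.

    ``ranked`` is a metric Series already ordered by decreasing value (see
    :func:`rank_genes`). Returns (es, running_sum Series, leading_edge ids).
    """
    ranked = pd.Series(ranked)
    gene_set = set(gene_set)
    unknown = gene_set - set(ranked.index)
    if unknown:
        raise ValueError(f"gene set members outside the universe: {sorted(unknown)[:5]}")
    hit = ranked.index.isin(gene_set)
    es, running = _es_core(ranked.to_numpy(dtype=float), hit, weight_p)
    idx = int(np.argmax(np.abs(running)))
    if es >= 0:
        leading = [g for g, h in zip(ranked.index[: idx + 1], hit[: idx + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.index[idx:], hit[idx:]) if h]
    return es, pd.Series(running, index=ranked.index, name="running_sum"), leading


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    leading_edge: list


def permutation_significance(
    matrix,
    groups: tuple,
    gene_sets: dict,
    n_perm: int = 1000,
    mode: str = "phenotype",
    seed: int = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Permutation p, NES and FDR q for every gene set.

    groups = (samples_a, samples_b); the ranking metric is signal-to-noise of
    a versus b. ``mode="phenotype"`` shuffles group labels; ``mode="gene_set"``
    draws random sets of matched size from the universe.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    group_a, group_b = list(groups[0]), list(groups[1])
    if mode == "phenotype" and min(len(group_a), len(group_b)) < 3:
        raise ValueError("phenotype permutation needs >= 3 samples per group")
    v = _values(matrix)
    rng = np.random.default_rng(seed)

    obs_ranked = rank_genes(signal_to_noise(v, group_a, group_b))
    universe = list(obs_ranked.index)
    hits_obs = {name: obs_ranked.index.isin(set(members)) for name, members in gene_sets.items()}
    obs = {}
    leading = {}
    for name, members in gene_sets.items():
        es, _run, lead = enrichment_score(obs_ranked, set(members) & set(universe), weight_p)
        obs[name] = es
        leading[name] = lead

    set_names = list(gene_sets)
    null_es = np.empty((n_perm, len(set_names)))
    if mode == "phenotype":
        combined = group_a + group_b
        for i in range(n_perm):
            perm = rng.permutation(combined)
            pa, pb = list(perm[: len(group_a)]), list(perm[len(group_a):])
            ranked = rank_genes(signal_to_noise(v, pa, pb))
            mvals = ranked.to_numpy(dtype=float)
            for j, name in enumerate(set_names):
                hit = ranked.index.isin(set(gene_sets[name]))
                null_es[i, j], _ = _es_core(mvals, hit, weight_p)
    elif mode == "gene_set":
        mvals = obs_ranked.to_numpy(dtype=float)
        n_universe = len(universe)
        for j, name in enumerate(set_names):
            k = int(hits_obs[name].sum())
            for i in range(n_perm):
                hit = np.zeros(n_universe, dtype=bool)
                hit[rng.choice(n_universe, size=k, replace=False)] = True
                null_es[i, j], _ = _es_core(mvals, hit, weight_p)
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")

    # per-set p and NES; same-sign normalization
    rows = []
    nes_obs = np.full(len(set_names), np.nan)
    nes_null = np.full_like(null_es, np.nan)
    for j, name in enumerate(set_names):
        es = obs[name]
        col = null_es[:, j]
        same = col * np.sign(es) > 0 if es != 0 else np.ones(len(col), dtype=bool)
        n_same = int(same.sum())
        extreme = int((np.abs(col[same]) >= abs(es)).sum())
        p = (1 + extreme) / (1 + n_same) if n_same else 1.0
        mean_same = np.abs(col[same]).mean() if n_same else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else 0.0
        nes_obs[j] = nes
        pos = col > 0
        neg = col < 0
        if pos.any():
            nes_null[pos, j] = col[pos] / np.abs(col[pos]).mean()
        if neg.any():
            nes_null[neg, j] = col[neg] / np.abs(col[neg]).mean()
        rows.append((name, int(hits_obs[name].sum()), es, nes, p))

    pool = nes_null[np.isfinite(nes_null)]
    fdr = []
    for j, name in enumerate(set_names):
        nes = nes_obs[j]
        if nes >= 0:
            null_frac_denom = (pool >= 0).sum()
            null_frac = (pool >= nes).sum() / null_frac_denom if null_frac_denom else 0.0
            obs_side = nes_obs[nes_obs >= 0]
            obs_frac = (obs_side >= nes).sum() / len(obs_side) if len(obs_side) else 1.0
        else:
            null_frac_denom = (pool < 0).sum()
            null_frac = (pool <= nes).sum() / null_frac_denom if null_frac_denom else 0.0
            obs_side = nes_obs[nes_obs < 0]
            obs_frac = (obs_side <= nes).sum() / len(obs_side) if len(obs_side) else 1.0
        q = float(np.clip(null_frac / obs_frac if obs_frac > 0 else 1.0, 0.0, 1.0))
        fdr.append(q)

    out = pd.DataFrame(rows, columns=["name", "size", "es", "nes", "p_perm"]).set_index("name")
    out["fdr_q"] = fdr
    out["leading_edge"] = [",".join(leading[name]) for name in out.index]
    return out


def exact_mannwhitney_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U and p (tie-free samples).

    The exact path used by :func:`subtype_enrichment` for small pooled sizes,
    exposed so it can be validated against direct enumeration at any n.
    """
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    return float(res.statistic), float(res.pvalue)


def subtype_enrichment(expression: pd.Series, class_labels: pd.Series) -> pd.DataFrame:
    """Per-class one-vs-rest Mann-Whitney test of a single gene's expression.

    Exact enumeration when n1 + n2 <= 12 and there are no ties; otherwise the
    normal approximation with tie correction. Classes with fewer than 2
    samples are skipped with a warning.
    """
    expression = pd.Series(expression)
    class_labels = pd.Series(class_labels).reindex(expression.index)
    classes = sorted(class_labels.dropna().unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    rows = []
    for cls in classes:
        x = expression[class_labels == cls]
        y = expression[class_labels != cls]
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"class {cls!r} has fewer than 2 samples; skipped")
            continue
        pooled = np.concatenate([x, y])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append((cls, len(x), len(y), float(res.statistic), float(res.pvalue), method))
    return pd.DataFrame(
        rows, columns=["class", "n_class", "n_rest", "U", "p_value", "method"]
    ).set_index("class")
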