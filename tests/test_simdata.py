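import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncscout import exprcore, simdata
from lncscout.cisreg import methylation_compare
from lncscout.survival import km_curve


def small_config(seed=0, **kw):
    params = dict(
        n_per_class={"BL": 20, "HER2": 8, "LA": 20, "LB": 10, "NL": 4, "NORMAL": 10},
        n_genes=200, n_planted=3, n_decoys=7, n_responsive=10,
    )
    params.update(kw)
    return simdata.CohortConfig(seed=seed, **params)


class TestGenerateCohort:
    def test_seeded_determinism(self):
        a = simdata.generate_cohort(small_config(seed=5))
        b = simdata.generate_cohort(small_config(seed=5))
        assert a.patients.values.equals(b.patients.values)
        assert a.cell_lines.values.equals(b.cell_lines.values)
        assert a.annotation.table.equals(b.annotation.table)
        assert a.truth.to_json() == b.truth.to_json()

    def test_different_seeds_differ(self):
        a = simdata.generate_cohort(small_config(seed=1))
        b = simdata.generate_cohort(small_config(seed=2))
        assert not a.patients.values.equals(b.patients.values)

    def test_dimensions_and_nonnegativity(self):
        c = simdata.generate_cohort(small_config())
        cfg = c.config
        assert c.patients.values.shape == (cfg.n_genes, sum(cfg.n_per_class.values()))
        assert (c.patients.values.to_numpy() >= 0).all()
        assert c.patients.values.to_numpy().dtype.kind == "i"
        assert len(c.annotation) == cfg.n_genes

    def test_planted_ids_exist_in_annotation(self):
        c = simdata.generate_cohort(small_config())
        for gid in c.truth.planted_candidate_ids:
            assert gid in c.annotation
            assert c.annotation.table.loc[gid, "biotype"] == "lncRNA"

    def test_neighbor_13kb_from_focal_end(self):
        c = simdata.generate_cohort(small_config())
        focal, nbr, _rho = c.truth.planted_neighbor_pair
        t = c.annotation.table
        assert t.loc[nbr, "chrom"] == t.loc[focal, "chrom"]
        assert t.loc[nbr, "start"] - t.loc[focal, "end"] == 13_000
        assert t.loc[nbr, "biotype"] == "protein_coding"

    def test_effects_off_planted_indistinguishable(self):
        """With all planted effects off, planted genes behave as baseline:
        BL-vs-NORMAL rank-test p is uniform across seeds."""
        ps = []
        for seed in range(50):
            cfg = small_config(seed=seed, expressor_fraction_bl=0.0, expressor_fraction_other=0.0)
            c = simdata.generate_cohort(cfg)
            gid = c.truth.planted_candidate_ids[0]
            bl = c.patients.values.loc[gid, c.patients.samples_of_class("BL")]
            norm = c.patients.values.loc[gid, c.patients.samples_of_class("NORMAL")]
            ps.append(stats.mannwhitneyu(bl, norm, alternative="two-sided").pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_bl_prevalence_near_forty_percent(self, desk_cohort, desk_fpkm):
        bl = desk_fpkm.samples_of_class("BL")
        prev = exprcore.prevalence(desk_fpkm, bl, 1.0)
        planted = prev[desk_cohort.truth.planted_candidate_ids]
        assert abs(planted.mean() - 0.40) <= 0.08

    def test_invalid_configs_raise(self):
        with pytest.raises(ValueError):
            small_config(n_planted=500)
        with pytest.raises(ValueError):
            small_config(dispersion=0.0)
        with pytest.raises(ValueError):
            small_config(expressor_fraction_bl=1.5)


class TestTruthLedger:
    def test_json_round_trip(self, demo_cohort):
        truth = demo_cohort.truth
        truth.planted_hazard_ratio = 3.0
        truth.compound_slopes = {"compound_01": -0.5, "compound_02": 0.0}
        restored = simdata.TruthLedger.from_json(truth.to_json())
        assert dataclasses.asdict(restored) == dataclasses.asdict(truth)

    def test_null_compound_slopes_exactly_zero(self):
        expr = pd.Series(np.arange(10.0), index=[f"c{i}" for i in range(10)])
        _tbl, slopes = simdata.generate_drug_response(expr, n_compounds=8, n_sensitive=2, seed=0)
        nulls = [s for s in slopes.values() if s == 0.0]
        assert len(nulls) == 6


class TestGenerateSurvival:
    def test_zero_censoring_all_events(self):
        expr = pd.Series(np.arange(20.0))
        tbl = simdata.generate_survival(expr, 2.0, censoring_rate=0.0, seed=1)
        assert (tbl["event"] == 1).all()

    def test_censoring_rate_calibrated_under_null(self):
        expr = pd.Series(np.arange(4000.0))
        tbl = simdata.generate_survival(expr, 1.0, censoring_rate=0.3, seed=2)
        assert abs((1 - tbl["event"].mean()) - 0.3) < 0.03

    def test_high_group_dies_faster_at_hr4(self):
        def km_median(sub):
            km = km_curve(sub["time"], sub["event"])
            below = km[km["survival"] <= 0.5]
            return below["time"].iloc[0] if len(below) else np.inf

        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            expr = pd.Series(np.random.default_rng(seed).normal(size=200))
            tbl = simdata.generate_survival(expr, 4.0, censoring_rate=0.2, seed=seed)
            wins += km_median(tbl[tbl["group"] == "high"]) < km_median(tbl[tbl["group"] == "low"])
        assert wins / n_seeds >= 0.95

    def test_errors(self):
        with pytest.raises(ValueError):
            simdata.generate_survival(pd.Series(dtype=float), 1.0)
        with pytest.raises(ValueError):
            simdata.generate_survival(pd.Series([1.0, 2.0]), -1.0)


class TestGenerateDrugResponse:
    def test_vanishing_noise_gives_perfect_negative_correlation(self):
        expr = pd.Series(np.arange(10.0), index=[f"c{i}" for i in range(10)])
        tbl, slopes = simdata.generate_drug_response(
            expr, n_compounds=3, n_sensitive=3, slope=-1.0, noise_sd=1e-9, seed=0
        )
        tbl["log10"] = np.log10(tbl["ic50_uM"])
        for name in slopes:
            sub = tbl[tbl["compound"] == name].set_index("cell_line")
            r = stats.pearsonr(expr, sub.loc[expr.index, "log10"])[0]
            assert r < -0.999999

    def test_same_seed_reproduces_table(self):
        expr = pd.Series(np.arange(5.0), index=list("abcde"))
        t1, _ = simdata.generate_drug_response(expr, seed=9)
        t2, _ = simdata.generate_drug_response(expr, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_errors(self):
        with pytest.raises(ValueError):
            simdata.generate_drug_response(pd.Series([1.0, 2.0]), seed=0)
        with pytest.raises(ValueError):
            simdata.generate_drug_response(pd.Series(np.arange(5.0)), n_compounds=2, n_sensitive=3)


class TestGenerateMethylation:
    @staticmethod
    def _classes(n_bl=15, n_other=15):
        idx = [f"s{i}" for i in range(n_bl + n_other)]
        return pd.Series(["BL"] * n_bl + ["LA"] * n_other, index=idx)

    def test_betas_bounded(self):
        for seed in range(5):
            b = simdata.generate_methylation(self._classes(), "BL", n_probes=10, seed=seed)
            arr = b.to_numpy()
            assert ((arr >= 0) & (arr <= 1)).all()

    def test_hypo_class_detected_at_default_effect(self):
        classes = self._classes()
        bl = list(classes.index[classes == "BL"])
        other = list(classes.index[classes != "BL"])
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            b = simdata.generate_methylation(classes, "BL", n_probes=20, seed=seed)
            res = methylation_compare(b, bl, other)
            hits += (res["p_value"] < 0.05) and (b[bl].mean().mean() < b[other].mean().mean())
        assert hits / n_seeds >= 0.95

    def test_zero_effect_p_uniform(self):
        classes = self._classes()
        bl = list(classes.index[classes == "BL"])
        other = list(classes.index[classes != "BL"])
        ps = []
        for seed in range(60):
            b = simdata.generate_methylation(classes, "BL", n_probes=20, seed=seed, effect=0.0)
            ps.append(methylation_compare(b, bl, other)["p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError, match="hypo_class"):
            simdata.generate_methylation(self._classes(), "XX", seed=0)


class TestGenerateGenesets:
    def test_determinism_and_truth_recording(self, demo_cohort):
        truth = demo_cohort.truth
        s1 = simdata.generate_genesets(truth, demo_cohort.annotation, n_sets=5, set_size=10, seed=3)
        s2 = simdata.generate_genesets(truth, demo_cohort.annotation, n_sets=5, set_size=10, seed=3)
        assert s1 == s2
        assert truth.responsive_set_name == "GS_RESPONSIVE"
        assert set(s1["GS_RESPONSIVE"]) <= set(truth.responsive_set_ids)

    def test_random_sets_exclude_planted_signal(self, demo_cohort):
        truth = demo_cohort.truth
        sets = simdata.generate_genesets(truth, demo_cohort.annotation, n_sets=6, set_size=10, seed=1)
        coupled = set(truth.responsive_set_ids) | set(truth.planted_candidate_ids)
        for name, members in sets.items():
            if name != "GS_RESPONSIVE":
                assert not (set(members) & coupled)

    def test_set_size_too_large_raises(self, demo_cohort):
        with pytest.raises(ValueError):
            simdata.generate_genesets(
                demo_cohort.truth, demo_cohort.annotation, n_sets=2,
                set_size=len(demo_cohort.annotation), seed=0,
            )
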