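"""SNP-set construction, scoring, AUC calibration, and state enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from ddagwas import (CohortData, SnpSetCatalog, StateAnnotation,
                     build_snp_sets, pair_state_enrichment, score_snp_set,
                     state_enrichment)
from ddagwas.snp_sets import ld_r2_from_haplotypes

from conftest import make_meta


def _meta(positions, chrom="1"):
    return pd.DataFrame({
        "chrom": [chrom] * len(positions),
        "snp": [f"s{i}" for i in range(len(positions))],
        "pos": positions, "a1": "A", "a2": "G"})


class TestBuildSnpSets:
    def test_window_assignment_boundaries(self):
        meta = _meta([100_000, 100_000 + 1])
        genes = pd.DataFrame({
            "chrom": ["1", "1"],
            "start": [140_000, 160_001],
            "end": [160_000, 170_000],
            "gene": ["G_in", "G_out"]})
        pathways = {"P1": ["G_in"], "P2": ["G_out"]}
        cat = build_snp_sets(meta, genes, pathways, window_bp=50_000,
                             min_snps=1)
        assert "s0" in cat.sets["P1"]          # 40 kb away
        assert "P2" not in cat.sets            # 60,001 bp > 50 kb

    def test_shared_gene_propagates_to_all_pathways(self):
        meta = _meta(list(range(10_000, 20_001, 500)))
        genes = pd.DataFrame({"chrom": ["1"], "start": [12_000],
                              "end": [14_000], "gene": ["SHARED"]})
        pathways = {f"P{k}": ["SHARED"] for k in range(3)}
        cat = build_snp_sets(meta, genes, pathways, window_bp=5_000,
                             min_snps=1)
        ref = cat.sets["P0"]
        assert cat.sets["P1"] == ref and cat.sets["P2"] == ref

    def test_min_snps_filter_and_determinism(self):
        meta = _meta(list(range(1000, 40_000, 1000)))
        genes = pd.DataFrame({
            "chrom": ["1", "1"], "start": [1000, 30_000],
            "end": [20_000, 30_500], "gene": ["BIG", "TINY"]})
        pathways = {"big": ["BIG"], "tiny": ["TINY"]}
        cat = build_snp_sets(meta, genes, pathways, window_bp=0,
                             min_snps=5)
        assert "big" in cat.sets and "tiny" not in cat.sets
        cat2 = build_snp_sets(meta, genes, dict(reversed(pathways.items())),
                              window_bp=0, min_snps=5)
        assert cat.sets == cat2.sets

    def test_empty_catalog_rejected(self):
        meta = _meta([1000])
        genes = pd.DataFrame({"chrom": ["2"], "start": [0], "end": [10],
                              "gene": ["G"]})
        with pytest.raises(ValueError):
            build_snp_sets(meta, genes, {"P": ["G"]}, min_snps=1)


class TestScoreSnpSet:
    def _null_cohort(self, n=1600, m=25, seed=0):
        rng = np.random.default_rng(seed)
        geno = rng.binomial(2, 0.3, (n, m)).astype(np.int8)
        pheno = np.tile([0, 1], n // 2).astype(np.int8)
        return CohortData(geno, pheno, make_meta(m))

    def test_null_set_auc_ci_contains_half(self):
        data = self._null_cohort()
        ids = [f"snp{i + 1}" for i in range(10)]
        sc = score_snp_set(ids, data, method="MF",
                           grid=[0.0, 0.5, 1.0], folds=4, seed=1)
        assert sc.ci[0] < 0.5 < sc.ci[1]
        assert sc.snp_count == 10

    def test_disjoint_null_sets_score_alike(self):
        data = self._null_cohort(seed=3)
        a = score_snp_set([f"snp{i}" for i in range(1, 11)], data,
                          method="independent", grid=[0.0], seed=5)
        b = score_snp_set([f"snp{i}" for i in range(11, 21)], data,
                          method="independent", grid=[0.0], seed=5)
        # AUC difference within combined CI half-widths
        spread = (a.ci[1] - a.ci[0]) / 2 + (b.ci[1] - b.ci[0]) / 2
        assert abs(a.auc - b.auc) < spread

    def test_missing_set_flagged(self):
        data = self._null_cohort()
        sc = score_snp_set(["absent1", "absent2"], data)
        assert sc.flagged and sc.p_estimate == 1.0


class TestEnrichment:
    def _proxies(self, snps, positions):
        return pd.DataFrame({"snp": snps, "proxy_chrom": "1",
                             "proxy_pos": positions, "r2": 1.0})

    def test_fully_active_binomial_tail(self):
        snps = [f"s{i}" for i in range(10)]
        prox = self._proxies(snps, np.arange(10) * 100 + 50)
        ann = StateAnnotation("E1", {"1": (np.array([0]),
                                          np.array([10_000]))}, 0.1)
        assert state_enrichment(snps, prox, ann) == \
            pytest.approx(1e-10, rel=1e-9)

    def test_background_level_observation_not_enriched(self):
        snps = [f"s{i}" for i in range(10)]
        # exactly half the proxies active, background 0.5
        prox = self._proxies(snps, [50] * 5 + [5_000_000] * 5)
        ann = StateAnnotation("E1", {"1": (np.array([0]),
                                          np.array([1000]))}, 0.5)
        assert state_enrichment(snps, prox, ann) >= 0.5

    def test_saturating_background(self):
        snps = [f"s{i}" for i in range(8)]
        prox = self._proxies(snps, [5_000_000] * 8)  # none active
        ann = StateAnnotation("E1", {"1": (np.array([0]),
                                          np.array([1000]))}, 0.999)
        assert state_enrichment(snps, prox, ann) == pytest.approx(1.0)

    def test_pair_enrichment_product_background(self):
        snps = [f"s{i}" for i in range(10)]
        prox = self._proxies(snps, np.arange(10) * 100 + 50)
        ann = StateAnnotation("E1", {"1": (np.array([0]),
                                          np.array([10_000]))}, 0.1)
        p = pair_state_enrichment([(s, s) for s in snps], prox, ann, ann)
        assert p == pytest.approx(1e-20, rel=1e-9)

    def test_pair_enrichment_symmetric_under_swap(self):
        snps = [f"s{i}" for i in range(6)]
        prox = self._proxies(snps, [50, 50, 5_000_000, 50, 50, 5_000_000])
        a = StateAnnotation("A", {"1": (np.array([0]),
                                        np.array([1000]))}, 0.2)
        b = StateAnnotation("B", {"1": (np.array([0]),
                                        np.array([2000]))}, 0.3)
        pairs = [("s0", "s1"), ("s2", "s3"), ("s4", "s5")]
        swapped = [(t, s) for s, t in pairs]
        assert pair_state_enrichment(pairs, prox, a, b) == \
            pytest.approx(pair_state_enrichment(swapped, prox, b, a))

    def test_null_annotation_pvalues_uniform(self):
        # active flags i.i.d. at the background frequency: enrichment p
        # over replicate SNP lists is approximately uniform
        rng = np.random.default_rng(17)
        bg = 0.3
        ps = []
        for _ in range(200):
            n_snps = 500
            active = rng.random(n_snps) < bg
            # one proxy per SNP placed in/out of the active interval
            pos = np.where(active, 500, 5_000_000)
            snps = [f"s{i}" for i in range(n_snps)]
            prox = self._proxies(snps, pos)
            ann = StateAnnotation("E", {"1": (np.array([0]),
                                             np.array([1000]))}, bg)
            ps.append(state_enrichment(snps, prox, ann))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_empty_list_rejected(self):
        ann = StateAnnotation("E", {}, 0.5)
        with pytest.raises(ValueError):
            state_enrichment([], pd.DataFrame(), ann)


class TestLdHelper:
    def test_r2_perfect_and_independent(self):
        rng = np.random.default_rng(19)
        h1 = (rng.random(2000) < 0.4).astype(int)
        h2 = h1.copy()
        h3 = (rng.random(2000) < 0.4).astype(int)
        r2 = ld_r2_from_haplotypes(np.column_stack([h1, h2, h3]))
        assert r2[0, 1] == pytest.approx(1.0)
        assert r2[0, 2] < 0.05


class TestCalibration:
    def test_auc_to_p_mapping_monotone_and_anchored(self):
        from ddagwas import calibrate_auc_to_p
        from ddagwas.snp_sets import annotate_scores
        rng = np.random.default_rng(23)
        n, m = 400, 40
        pheno = np.tile([0, 1], n // 2).astype(np.int8)
        geno = np.empty((n, m), dtype=np.int8)
        for i in range(m):
            if i < 10:
                d = 0.04   # two weakly associated sets
            elif i < 20:
                d = 0.10   # two strongly associated sets
            else:
                d = 0.0    # four null sets
            geno[:, i] = rng.binomial(2, np.where(pheno == 1, 0.30 + d,
                                                  0.30))
        data = CohortData(geno, pheno, make_meta(m))
        names = [f"snp{i + 1}" for i in range(m)]
        cat = SnpSetCatalog(
            sets={f"set{k}": names[5 * k: 5 * k + 5] for k in range(8)})
        scores = [score_snp_set(ids, data, method="independent",
                                grid=[0.0], folds=3, seed=2, set_name=nm)
                  for nm, ids in cat.sets.items()]
        calib = calibrate_auc_to_p(scores, data, n_perm=199, seed=3,
                                   method="independent", folds=3,
                                   catalog=cat)
        assert calib.slope > 0.0
        assert calib.p_value(0.60) <= calib.p_value(0.55)
        assert calib.p_value(0.50) > 0.05   # null AUC maps near p ~ 1
        assert 0.52 < calib.auc_threshold < 1.0
        annotate_scores(scores, calib)
        assert all(sc.p_estimate is not None for sc in scores)
        strong = [sc for sc in scores if sc.auc > calib.auc_threshold]
        assert all(sc.passes_bonferroni for sc in strong)

    def test_too_few_informative_points_rejected(self):
        from ddagwas import calibrate_auc_to_p
        from ddagwas.snp_sets import SetScore
        data = None
        scores = [SetScore(f"s{k}", 0.5, (0.4, 0.6), 0.5, (0.4, 0.6), 5)
                  for k in range(3)]
        with pytest.raises(ValueError, match="at least 5"):
            calibrate_auc_to_p(scores, data)
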