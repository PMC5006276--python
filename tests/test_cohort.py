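"""Loading, QC, encoding, and empirical-moment computation."""

import math
from fractions import Fraction

import numpy as np
import pytest

from ddagwas import (CohortData, EncodedMatrix, empirical_moments, encode,
                     hwe_exact_pvalue, load_genotypes, qc_filter)
from ddagwas.cohort import DegenerateCohortError, EmptyPanelError
from ddagwas.models import MISSING
from ddagwas.plink import PlinkParseError, write_bed, write_ped

from conftest import make_meta


class TestLoading:
    def test_ped_fixture_maps_phenotypes_and_missing(self, tiny_ped):
        data = load_genotypes(tiny_ped, "ped")
        assert (data.n0, data.n1, data.m) == (2, 2, 2)
        assert data.genotypes[3, 1] == MISSING  # "0 0" entry
        # sample 1: "A G" -> one copy of first-seen allele A
        assert data.genotypes[0, 0] == 1
        assert data.genotypes[2, 0] == 0  # "G G"

    def test_unknown_phenotype_codes_drop_samples(self, tmp_path):
        (tmp_path / "p.map").write_text("1 snp1 0 100\n")
        (tmp_path / "p.ped").write_text(
            "F1 I1 0 0 1 1 A A\nF2 I2 0 0 1 2 A G\n"
            "F3 I3 0 0 1 -9 G G\nF4 I4 0 0 1 0 A G\n"
            "F5 I5 0 0 1 2 G G\n")
        data = load_genotypes(tmp_path / "p", "ped")
        assert data.n == 3 and data.n0 == 1 and data.n1 == 2

    def test_malformed_line_names_line_number(self, tmp_path):
        (tmp_path / "bad.map").write_text("1 snp1 0 100\n")
        (tmp_path / "bad.ped").write_text(
            "F1 I1 0 0 1 1 A A\nF2 I2 0 0 1 2 A\n")
        with pytest.raises(PlinkParseError, match="line 2"):
            load_genotypes(tmp_path / "bad", "ped")

    def test_degenerate_cohort_rejected(self, tmp_path):
        (tmp_path / "d.map").write_text("1 snp1 0 100\n")
        (tmp_path / "d.ped").write_text(
            "F1 I1 0 0 1 2 A A\nF2 I2 0 0 1 2 A G\n")
        with pytest.raises(DegenerateCohortError):
            load_genotypes(tmp_path / "d", "ped")

    def test_bed_round_trip_matches_ped_twin(self, tmp_path):
        """An independently hand-packed .bed equals its .ped twin."""
        # first sample heterozygous everywhere so the .ped reader's
        # first-seen allele coincides with the .bim a1 column
        geno = np.array([[1, 1, 1], [0, 2, 0], [2, 0, MISSING],
                         [1, 1, 2], [0, 2, 1]], dtype=np.int8)
        pheno = np.array([0, 0, 1, 1, 1], dtype=np.int8)
        meta = make_meta(3)
        write_ped(tmp_path / "twin", geno, pheno, meta)
        # hand-pack the .bed body: 00=2 copies of a1, 10=het, 11=0, 01=miss
        code = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}
        body = bytearray([0x6C, 0x1B, 0x01])
        for i in range(3):
            cs = [code[int(g)] for g in geno[:, i]] + [0, 0, 0]
            for k in range(0, 8, 4):
                body.append(cs[k] | (cs[k + 1] << 2) | (cs[k + 2] << 4)
                            | (cs[k + 3] << 6))
        (tmp_path / "twin.bed").write_bytes(bytes(body))
        with open(tmp_path / "twin.bim", "w") as fh:
            for _, r in meta.iterrows():
                fh.write(f"{r['chrom']}\t{r['snp']}\t0\t{r['pos']}\t"
                         f"{r['a1']}\t{r['a2']}\n")
        with open(tmp_path / "twin.fam", "w") as fh:
            for k in range(5):
                fh.write(f"F{k+1} I{k+1} 0 0 0 {int(pheno[k]) + 1}\n")
        ped = load_genotypes(tmp_path / "twin", "ped")
        bed = load_genotypes(tmp_path / "twin", "bed")
        np.testing.assert_array_equal(ped.genotypes, bed.genotypes)
        np.testing.assert_array_equal(ped.phenotypes, bed.phenotypes)

    def test_package_bed_writer_round_trips(self, tmp_path):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, (17, 4)).astype(np.int8)
        geno[3, 2] = MISSING
        pheno = (rng.random(17) < 0.5).astype(np.int8)
        pheno[:2] = [0, 1]
        write_bed(tmp_path / "rt", geno, pheno, make_meta(4))
        back = load_genotypes(tmp_path / "rt", "bed")
        np.testing.assert_array_equal(back.genotypes, geno)


def brute_force_hwe(n_hom_minor, n_het, n_hom_major):
    """Independent exact-test oracle using rational arithmetic."""
    n = n_hom_minor + n_het + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:
        n_minor = 2 * n - n_minor
        n_hom_minor = n - n_het - n_hom_minor

    def prob(h):
        r = (n_minor - h) // 2
        c = n - h - r
        return Fraction(math.factorial(n) * 2 ** h
                        * math.factorial(n_minor)
                        * math.factorial(2 * n - n_minor),
                        math.factorial(h) * math.factorial(r)
                        * math.factorial(c) * math.factorial(2 * n))

    hs = range(n_minor % 2, n_minor + 1, 2)
    probs = {h: prob(h) for h in hs}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestQC:
    def _cohort(self, geno, pheno, m=None):
        m = geno.shape[1] if m is None else m
        return CohortData(geno, pheno, make_meta(m))

    def test_hwe_exact_matches_brute_force(self):
        cases = [(2, 14, 84), (5, 10, 85), (0, 50, 50), (50, 0, 50),
                 (1, 1, 98), (10, 40, 50)]
        for hm, het, hM in cases:
            assert hwe_exact_pvalue(hm, het, hM) == pytest.approx(
                brute_force_hwe(hm, het, hM), abs=1e-12)

    def test_maf_threshold(self):
        rng = np.random.default_rng(1)
        n = 1000
        geno = np.column_stack([
            rng.binomial(2, p, n) for p in (0.005, 0.05, 0.30)
        ]).astype(np.int8)
        geno[:, 0] = 0
        geno[0, 0] = 1  # pooled MAF 0.0005 -> removed
        pheno = np.tile([0, 1], n // 2).astype(np.int8)
        out, report = qc_filter(self._cohort(geno, pheno), maf_min=0.01,
                                hwe_p_min=0.0, miss_max=1.0)
        assert out.m == 2
        assert bool(report["fail_maf"][0])

    def test_hwe_filter_removes_het_deficient_snp(self):
        # controls: (AA=50, Aa=0, aa=50) -> exact HWE p << 1e-6
        ctrl = np.repeat([0, 2], [50, 50]).astype(np.int8)
        case = np.repeat([0, 1, 2], [25, 50, 25]).astype(np.int8)
        good = np.tile([0, 1, 2, 1], 25).astype(np.int8)
        geno = np.column_stack([np.concatenate([ctrl, case]),
                                np.concatenate([good, good])])
        pheno = np.repeat([0, 1], 100).astype(np.int8)
        assert hwe_exact_pvalue(50, 0, 50) < 1e-6
        out, report = qc_filter(self._cohort(geno, pheno), maf_min=0.0,
                                hwe_p_min=1e-6, miss_max=1.0)
        assert out.m == 1 and bool(report["fail_hwe"][0])

    def test_missingness_filter(self):
        rng = np.random.default_rng(2)
        geno = rng.integers(0, 3, (200, 2)).astype(np.int8)
        geno[:20, 0] = MISSING  # 10 % missing
        pheno = np.tile([0, 1], 100).astype(np.int8)
        out, report = qc_filter(self._cohort(geno, pheno), maf_min=0.0,
                                hwe_p_min=0.0, miss_max=0.05)
        assert out.m == 1 and bool(report["fail_miss"][0])

    def test_idempotent_and_minor_allele_oriented(self):
        rng = np.random.default_rng(3)
        geno = np.column_stack([
            rng.binomial(2, p, 400) for p in (0.1, 0.8, 0.45, 0.95)
        ]).astype(np.int8)
        pheno = np.tile([0, 1], 200).astype(np.int8)
        once, _ = qc_filter(self._cohort(geno, pheno))
        twice, _ = qc_filter(once)
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)
        freq = (once.genotypes.astype(float).mean(axis=0)) / 2.0
        assert (freq <= 0.5 + 1e-12).all()

    def test_all_removed_raises(self):
        geno = np.zeros((100, 1), dtype=np.int8)
        pheno = np.tile([0, 1], 50).astype(np.int8)
        with pytest.raises(EmptyPanelError):
            qc_filter(self._cohort(geno, pheno), maf_min=0.01)


class TestEncode:
    @pytest.mark.parametrize("model,expected", [
        ("dominant", [0, 1, 1]),
        ("recessive", [0, 0, 1]),
        ("genotypic", [0, 1, 2]),
    ])
    def test_encoding_maps(self, model, expected):
        geno = np.array([[0], [1], [2]], dtype=np.int8)
        pheno = np.array([0, 1, 1], dtype=np.int8)
        enc = encode(CohortData(geno, pheno, make_meta(1)), model)
        np.testing.assert_array_equal(enc.values.ravel(), expected)

    def test_unknown_model_rejected(self):
        data = CohortData(np.zeros((2, 1), dtype=np.int8),
                          np.array([0, 1], dtype=np.int8), make_meta(1))
        with pytest.raises(ValueError, match="unknown encoding model"):
            encode(data, "additive")

    def test_missing_imputed_to_pooled_mode(self):
        geno = np.array([[2], [2], [2], [0], [MISSING]], dtype=np.int8)
        pheno = np.array([0, 0, 1, 1, 1], dtype=np.int8)
        enc = encode(CohortData(geno, pheno, make_meta(1)), "genotypic")
        assert enc.values[4, 0] == 2  # modal pooled genotype


class TestMoments:
    def test_binary_mean_and_identical_columns(self):
        vals = np.array([[0, 0], [1, 1], [1, 1], [0, 0]], dtype=np.int8)
        mom = empirical_moments(EncodedMatrix(vals, "dominant"),
                                np.array([0, 1, 0, 1]), "pooled")
        assert mom.f_single[0] == pytest.approx(0.5)
        assert mom.f_pair[0, 1] == pytest.approx(mom.f_single[0])

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        vals = (rng.random((100, 5)) < 0.4).astype(np.int8)
        labels = (rng.random(100) < 0.5).astype(np.int8)
        labels[:2] = [0, 1]
        mom = empirical_moments(EncodedMatrix(vals, "dominant"), labels,
                                "case")
        rows = vals[labels == 1]
        for i in range(5):
            for j in range(5):
                acc = sum(int(r[i]) * int(r[j]) for r in rows) / len(rows)
                if i == j:
                    acc = sum(int(r[i]) for r in rows) / len(rows)
                assert mom.f_pair[i, j] == pytest.approx(acc)

    def test_genotypic_levels_and_empty_group(self):
        vals = np.array([[0], [1], [2], [2]], dtype=np.int8)
        labels = np.array([1, 1, 1, 1])
        mom = empirical_moments(EncodedMatrix(vals, "genotypic"), labels,
                                "case")
        np.testing.assert_allclose(mom.f_single[0], [0.25, 0.5])
        with pytest.raises(Exception):
            empirical_moments(EncodedMatrix(vals, "genotypic"), labels,
                              "control")
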