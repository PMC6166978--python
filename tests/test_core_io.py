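"""Phased-panel IO, Hardy-Weinberg exact test, and QC filtering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_panel
from mendelbalance import core_io
from mendelbalance.core_io import (
    MISSING, ValidationError, hwe_exact_test, load_phased_genotypes,
    qc_filter, write_phased_tsv, write_phased_vcf,
)


# ---------------------------------------------------------------------------
# enumeration oracle for the HWE exact test
# ---------------------------------------------------------------------------

def hwe_oracle(n_aa, n_ab, n_bb):
    """Textbook conditional enumeration: P(tables no more probable than
    observed | allele counts), probabilities from exact factorials."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n - na
    def prob(h):
        haa = (na - h) // 2
        hbb = (nb - h) // 2
        return (math.factorial(n) // (math.factorial(haa) * math.factorial(h)
                                      * math.factorial(hbb))) * 2 ** h \
            * math.factorial(na) * math.factorial(nb) / math.factorial(2 * n)
    hets = range(min(na, nb) % 2, min(na, nb) + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestHWEExact:
    def test_balanced_marker_not_extreme(self):
        # call rate 1, MAF 0.30, visibly near HW proportions
        assert hwe_exact_test(45, 50, 5) > 1e-3

    def test_no_heterozygotes_is_extreme(self):
        p = hwe_exact_test(50, 0, 50)
        assert p < 1e-6
        assert p == pytest.approx(hwe_oracle(50, 0, 50), rel=1e-9)

    @pytest.mark.parametrize("counts", [
        (45, 50, 5), (50, 0, 50), (10, 10, 10), (0, 5, 95), (3, 0, 0),
        (12, 40, 48), (60, 30, 10), (1, 1, 1), (0, 100, 0),
    ])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts),
                                                        rel=1e-9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_oracle_agreement_up_to_200_alleles(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(hwe_oracle(a, b, c),
                                                        rel=1e-9)


# ---------------------------------------------------------------------------
# phased genotype IO
# ---------------------------------------------------------------------------

def _write_tsv(path, marker_lines, header, rows):
    with open(path, "w") as fh:
        for ml in marker_lines:
            fh.write(ml + "\n")
        fh.write(header + "\n")
        for r in rows:
            fh.write(r + "\n")


class TestPhasedIO:
    def test_tsv_fixture_roundtrips_alleles(self, tmp_path):
        p = tmp_path / "panel.tsv"
        _write_tsv(p,
                   ["#marker\tm1\t1\t100\tA\tB", "#marker\tm2\t1\t200\tC\tG"],
                   "animal\thap\tm1\tm2",
                   ["pig1\t1\tA\tG", "pig1\t2\tA\tC"])
        panel = load_phased_genotypes(p)
        assert panel.animals == ["pig1"]
        # hap1 = [A, B-allele(G)], hap2 = [A, A-allele(C)]
        assert panel.hap1[0].tolist() == [0, 1]
        assert panel.hap2[0].tolist() == [0, 0]

    def test_vcf_phased_genotypes(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\tm1\tA\tT\t.\t.\t.\tGT\t0|1\t1|1\n")
        panel = load_phased_genotypes(p)
        assert panel.hap1[:, 0].tolist() == [0, 1]
        assert panel.hap2[:, 0].tolist() == [1, 1]

    def test_unphased_vcf_rejected_naming_record(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\tm1\tA\tT\t.\t.\t.\tGT\t0/1\n")
        with pytest.raises(ValidationError, match="1:100"):
            load_phased_genotypes(p)

    def test_duplicate_marker_rejected(self, tmp_path):
        p = tmp_path / "panel.tsv"
        _write_tsv(p,
                   ["#marker\tm1\t1\t100\tA\tB", "#marker\tm1\t1\t200\tA\tB"],
                   "animal\thap\tm1\tm1", ["x\t1\tA\tA", "x\t2\tA\tA"])
        with pytest.raises(ValidationError, match="duplicate"):
            load_phased_genotypes(p)

    @pytest.mark.parametrize("writer,fname", [
        (write_phased_tsv, "p.tsv"), (write_phased_vcf, "p.vcf")])
    def test_write_read_roundtrip_identity(self, tmp_path, writer, fname):
        rng = np.random.default_rng(0)
        h = rng.integers(0, 2, size=(2, 8, 50)).astype(np.int8)
        h[0, 0, 3] = MISSING
        h[1, 0, 3] = MISSING
        panel = make_panel(h[0], h[1])
        writer(panel, tmp_path / fname)
        back = load_phased_genotypes(tmp_path / fname)
        assert back.animals == panel.animals
        np.testing.assert_array_equal(back.hap1, panel.hap1)
        np.testing.assert_array_equal(back.hap2, panel.hap2)
        pd.testing.assert_frame_equal(back.markers.table, panel.markers.table)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def _qc_panel(rng, n=100, m=12):
    h1 = rng.integers(0, 2, size=(n, m)).astype(np.int8)
    h2 = rng.integers(0, 2, size=(n, m)).astype(np.int8)
    return make_panel(h1, h2)


class TestQCFilter:
    def test_high_missingness_animal_removed_before_marker_stats(self):
        rng = np.random.default_rng(1)
        panel = _qc_panel(rng)
        # animal 0: 25% missing; its missing calls would also sink marker 0's
        # call rate if animals were not removed first
        k = panel.hap1.shape[1] // 4 + 1
        panel.hap1[0, :k] = MISSING
        out, report = qc_filter(panel)
        assert "S0" not in out.animals
        assert report.removed_animals["reason"].tolist() == ["missingness"]

    def test_monomorphic_marker_fails_maf(self):
        rng = np.random.default_rng(2)
        panel = _qc_panel(rng)
        panel.hap1[:, 2] = 0
        panel.hap2[:, 2] = 0
        out, report = qc_filter(panel)
        removed = report.removed_markers.set_index("marker_id")
        assert removed.loc["M2", "reason"] == "maf"

    def test_hwe_failure_removed(self):
        rng = np.random.default_rng(3)
        panel = _qc_panel(rng)
        # marker 5: half AA, half BB, zero heterozygotes
        panel.hap1[:, 5] = np.repeat([0, 1], 50)
        panel.hap2[:, 5] = np.repeat([0, 1], 50)
        out, report = qc_filter(panel)
        removed = report.removed_markers.set_index("marker_id")
        assert removed.loc["M5", "reason"] == "hwe"
        assert removed.loc["M5", "value"] < 1e-6

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        panel = _qc_panel(rng)
        panel.hap1[0, :4] = MISSING
        panel.hap1[:, 2] = 0
        panel.hap2[:, 2] = 0
        once, _ = qc_filter(panel)
        twice, rep2 = qc_filter(once)
        assert twice.animals == once.animals
        np.testing.assert_array_equal(twice.hap1, once.hap1)
        assert len(rep2.removed_animals) == 0 and len(rep2.removed_markers) == 0

    def test_filtering_preserves_coordinates_and_ids(self):
        rng = np.random.default_rng(5)
        panel = _qc_panel(rng)
        panel.hap1[:, 2] = 0
        panel.hap2[:, 2] = 0
        out, _ = qc_filter(panel)
        kept = out.markers.table.set_index("marker_id")
        orig = panel.markers.table.set_index("marker_id")
        assert (kept["pos_bp"] == orig.loc[kept.index, "pos_bp"]).all()
        assert out.animals == panel.animals

    def test_threshold_validation(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            qc_filter(_qc_panel(rng), maf_min=1.5)


# ---------------------------------------------------------------------------
# tabular loaders
# ---------------------------------------------------------------------------

class TestTables:
    def _write(self, tmp_path, name, text):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_pedigree_founders_flagged(self, tmp_path):
        p = self._write(tmp_path, "ped.csv",
                        "animal,sire,dam,sex,birth_date\n"
                        "F1,,,male,2006-01-01\n"
                        "F2,,,female,2006-01-02\n"
                        "K1,F1,F2,male,2007-06-01\n")
        ped = core_io.load_pedigree(p)
        assert ped.set_index("animal")["is_founder"].tolist() == [True, True, False]

    def test_cyclic_pedigree_rejected(self, tmp_path):
        p = self._write(tmp_path, "ped.csv",
                        "animal,sire,dam,sex,birth_date\n"
                        "A,B,,male,2006-01-01\n"
                        "B,A,,male,2006-01-01\n")
        with pytest.raises(ValidationError, match="cycle"):
            core_io.load_pedigree(p)

    def test_litter_with_mummies_beyond_tnb_accepted(self, tmp_path):
        # mummies sit in their own column, outside TNB
        p = self._write(tmp_path, "lit.csv",
                        "litter_id,sire,dam,farm,parity,tnb,nba,stillborn,mummified,date\n"
                        "CC2,S1,D1,2,1,12,11,1,3,2017-05-01\n")
        lit = core_io.load_litters(p)
        assert lit.loc[0, ["tnb", "nba", "stillborn", "mummified"]].tolist() == \
            [12, 11, 1, 3]
        with_mum = core_io.load_litters(p, mummies_in_tnb=True)
        assert with_mum.loc[0, "tnb"] == 15

    def test_litter_count_invariant_enforced(self, tmp_path):
        p = self._write(tmp_path, "lit.csv",
                        "litter_id,sire,dam,farm,parity,tnb,nba,stillborn,mummified,date\n"
                        "BAD,S1,D1,1,1,12,13,0,0,2017-05-01\n")
        with pytest.raises(ValidationError, match="BAD"):
            core_io.load_litters(p)
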