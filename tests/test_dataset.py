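"""Variant records, VCF reading, and labeling/filter rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sscnova import (
    LabeledDataset,
    VariantRecord,
    curated_negative_candidates,
    intersect_positive,
    random_genome_negatives,
    read_vcf,
    select_negatives,
    split_dataset,
)
from sscnova.variants import ValidationError, VcfParseError, write_vcf


def _table(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "p_value", "af"]
    )


class TestVariantRecord:
    def test_invariants(self):
        with pytest.raises(ValueError):
            VariantRecord("1", 10, "A", "A")
        with pytest.raises(ValueError):
            VariantRecord("1", 10, "N", "A")
        with pytest.raises(ValueError):
            VariantRecord("1", 10, "A", "T", af=1.5)
        r = VariantRecord("1", 10, "AC", "A")  # indel-style alleles allowed
        assert r.key == ("1", 10, "AC", "A")

    def test_duplicate_keys_rejected_in_dataset(self):
        r = VariantRecord("1", 10, "A", "T")
        with pytest.raises(ValueError, match="duplicate"):
            LabeledDataset([r, r], [1, 1])


class TestReadVcf:
    def test_toy_vcf(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\trs1\tA\tG\t.\t.\t.\n"
            "chr1\t200\t.\tC\tT\t.\t.\t.\n"
            "chr2\t50\trs3\tG\tA\t.\t.\t.\n"
        )
        recs = read_vcf(p)
        assert [(r.chrom, r.pos, r.ref, r.alt) for r in recs] == [
            ("chr1", 100, "A", "G"), ("chr1", 200, "C", "T"), ("chr2", 50, "G", "A"),
        ]
        assert recs[0].id == "rs1" and recs[1].id == "."

    def test_multiallelic_split(self, tmp_path):
        p = tmp_path / "m.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\trs1\tC\tA,T\t.\t.\t.\n"
        )
        recs = read_vcf(p)
        assert [(r.pos, r.ref, r.alt) for r in recs] == [(100, "C", "A"), (100, "C", "T")]

    def test_missing_header(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("chr1\t100\trs1\tA\tG\t.\t.\t.\n")
        with pytest.raises(VcfParseError, match="header"):
            read_vcf(p)

    def test_malformed_pos(self, tmp_path):
        p = tmp_path / "bad2.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\tabc\trs1\tA\tG\t.\t.\t.\n"
        )
        with pytest.raises(VcfParseError):
            read_vcf(p)


class TestIntersectPositive:
    def test_set_identity(self):
        a = [("1", 1, "A", "T"), ("1", 2, "A", "T"), ("1", 3, "A", "T")]
        b = [("1", 2, "A", "T"), ("1", 3, "A", "T"), ("1", 4, "A", "T")]
        ds = intersect_positive(a, b)
        assert [r.pos for r in ds.records] == [2, 3]
        assert (ds.labels == 1).all()

    def test_disjoint_and_identical(self):
        a = [("1", 1, "A", "T")]
        assert len(intersect_positive(a, [("2", 1, "A", "T")])) == 0
        assert len(intersect_positive(a, a)) == 1


class TestSelectNegatives:
    def test_paper_filter_rule(self):
        t = _table([
            ("1", 1, "A", "T", 0.05, 0.4),   # P too small -> excluded
            ("1", 2, "A", "T", 0.2, 0.35),   # both pass -> included
            ("1", 3, "A", "T", 0.1, 0.4),    # P boundary (strict) -> excluded
            ("1", 4, "A", "T", 0.2, 0.3),    # AF boundary (strict) -> excluded
        ])
        ds = select_negatives(t)
        assert [r.pos for r in ds.records] == [2]
        assert (ds.labels == 0).all()

    def test_missing_values_error(self):
        t = _table([("1", 1, "A", "T", np.nan, 0.4)])
        with pytest.raises(ValidationError, match="missing"):
            select_negatives(t)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0.01, 0.99)),
                    min_size=1, max_size=30))
    def test_matches_brute_force_scan(self, pairs):
        rows = [("1", i + 1, "A", "T", p, af) for i, (p, af) in enumerate(pairs)]
        ds = select_negatives(_table(rows))
        brute = [r for r in rows if r[4] > 0.1 and r[5] > 0.3]
        assert len(ds) == len(brute)

    def test_idempotent(self):
        sig_rows = [("1", i, "A", "T", 0.5, 0.5) for i in range(1, 8)]
        other = [("1", 10, "A", "T", 0.01, 0.5)]
        once = select_negatives(_table(sig_rows + other))
        twice_input = pd.DataFrame({
            "chrom": [r.chrom for r in once.records],
            "pos": [r.pos for r in once.records],
            "ref": [r.ref for r in once.records],
            "alt": [r.alt for r in once.records],
            "p_value": [r.p_value for r in once.records],
            "af": [r.af for r in once.records],
        })
        assert len(select_negatives(twice_input)) == len(once)


class TestSplitDataset:
    def _ds(self, n):
        return LabeledDataset(
            [VariantRecord("1", i + 1, "A", "T") for i in range(n)],
            np.arange(n) % 2,
        )

    def test_eighty_twenty(self):
        train, test = split_dataset(self._ds(10), 0.2, seed=0)
        assert (len(train), len(test)) == (8, 2)

    def test_partition_laws(self):
        ds = self._ds(23)
        train, test = split_dataset(ds, 0.2, seed=5)
        tk, sk = set(train.keys()), set(test.keys())
        assert tk | sk == set(ds.keys())
        assert tk & sk == set()

    def test_deterministic(self):
        ds = self._ds(15)
        a = split_dataset(ds, 0.2, seed=3)
        b = split_dataset(ds, 0.2, seed=3)
        assert a[0].keys() == b[0].keys() and a[1].keys() == b[1].keys()

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_dataset(self._ds(10), 1.2, seed=0)


class TestCuratedNegatives:
    POS = [VariantRecord("chr1", 10_000, "A", "T")]

    def _cand(self, pos, cons, af):
        return VariantRecord("chr1", pos, "G", "C", conservation=cons, af=af)

    def test_window_conservation_af_rules(self):
        pool = [
            self._cand(11_500, 0.2, 0.4),  # 1500 bp away -> excluded
            self._cand(10_800, 0.6, 0.4),  # conserved -> excluded
            self._cand(10_800, 0.2, 0.4),  # all rules pass -> included
            self._cand(10_800, 0.2, 0.2),  # AF too low -> excluded
            self._cand(9_000, 0.2, 0.4),   # exactly 1000 bp -> included
        ]
        ds = curated_negative_candidates(self.POS, pool)
        assert sorted(r.pos for r in ds.records) == [9_000, 10_800]

    def test_positive_never_retained(self):
        pool = [VariantRecord("chr1", 10_000, "A", "T", conservation=0.1, af=0.4)]
        assert len(curated_negative_candidates(self.POS, pool)) == 0

    def test_missing_annotation_errors(self):
        pool = [VariantRecord("chr1", 10_100, "G", "C")]
        with pytest.raises(ValidationError):
            curated_negative_candidates(self.POS, pool)


class TestRandomGenomeNegatives:
    def test_min_dist_respected(self):
        pos = [VariantRecord("chr1", 5_000, "A", "T")]
        ds = random_genome_negatives(
            5, {"chr1": 10_000, "chr2": 10_000}, pos, min_dist=1000, seed=0
        )
        assert len(ds) == 5
        for r in ds.records:
            if r.chrom == "chr1":
                assert abs(r.pos - 5_000) >= 1000

    def test_deterministic(self):
        pos = [VariantRecord("chr1", 5_000, "A", "T")]
        a = random_genome_negatives(5, {"chr1": 10_000}, pos, 500, seed=4)
        b = random_genome_negatives(5, {"chr1": 10_000}, pos, 500, seed=4)
        assert a.keys() == b.keys()

    def test_infeasible_errors(self):
        pos = [VariantRecord("chr1", 500, "A", "T")]
        with pytest.raises(RuntimeError, match="attempts"):
            random_genome_negatives(
                3, {"chr1": 900}, pos, min_dist=2000, seed=0,
                max_attempts_per_site=50,
            )


def test_write_vcf_sorted_within_chrom(tmp_path):
    recs = [
        VariantRecord("chr1", 300, "A", "T"),
        VariantRecord("chr1", 100, "G", "C"),
    ]
    p = tmp_path / "s.vcf"
    write_vcf(recs, p)
    lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
    assert [int(l.split("\t")[1]) for l in lines] == [100, 300]
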