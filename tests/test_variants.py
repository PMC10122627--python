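"""VCF reading, multiallelic splitting and site-quality filters."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from varburden import (
    CaseCohort,
    CaseVariant,
    RawRecord,
    VcfFormatError,
    filter_mean_depth,
    filter_qd,
    merge_cohorts,
    read_case_vcf,
    split_multiallelic,
    write_case_vcf,
)
from varburden.variants import MISSING

from conftest import write_vcf


class TestReadCaseVcf:
    def test_direct_read_through(self, tmp_path):
        path = write_vcf(
            tmp_path / "a.vcf",
            "1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\n"
            "1\t350\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\n",
        )
        cohort = read_case_vcf(path, regions=[("1", 0, 1000)])
        assert cohort.n_cases == 3
        assert cohort.samples == ["S1", "S2", "S3"]
        assert len(cohort.variants) == 2
        np.testing.assert_array_equal(cohort.variants[0].dosages, [1, 0, 2])

    def test_missing_genotype_becomes_missing_dosage(self, tmp_path):
        path = write_vcf(
            tmp_path / "a.vcf", "1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\n"
        )
        v = read_case_vcf(path).variants[0]
        assert v.dosages[0] == MISSING
        assert v.dosages[1] == 1

    def test_triallelic_record_splits_into_two(self, tmp_path):
        path = write_vcf(
            tmp_path / "a.vcf", "1\t150\t.\tA\tC,T\t.\tPASS\t.\tGT\t1/2\t0/1\t2/2\n"
        )
        variants = read_case_vcf(path).variants
        assert len(variants) == 2
        assert {(v.chrom, v.pos, v.ref) for v in variants} == {("1", 150, "A")}
        by_alt = {v.alt: v for v in variants}
        np.testing.assert_array_equal(by_alt["C"].dosages, [1, 1, 0])
        np.testing.assert_array_equal(by_alt["T"].dosages, [1, 0, 2])

    def test_per_allele_consequences_from_csq(self, tmp_path):
        path = write_vcf(
            tmp_path / "a.vcf",
            "1\t150\t.\tA\tC,T\t.\tPASS\t"
            "CSQ=C|missense_variant,T|synonymous_variant\tGT\t0/1\t0/2\t0/0\n",
        )
        by_alt = {v.alt: v for v in read_case_vcf(path).variants}
        assert by_alt["C"].consequences == {"missense_variant"}
        assert by_alt["T"].consequences == {"synonymous_variant"}

    def test_no_gt_header_is_format_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##INFO=<ID=X,Number=1,Type=Integer,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with pytest.raises(VcfFormatError):
            read_case_vcf(str(path))

    def test_unknown_region_contig_skipped_with_warning(self, tmp_path, caplog):
        path = write_vcf(
            tmp_path / "a.vcf", "1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
        )
        with caplog.at_level("WARNING"):
            cohort = read_case_vcf(path, regions=[("chrUn", 0, 10)])
        assert cohort.variants == []
        assert any("contig" in r.message for r in caplog.records)

    def test_region_restriction(self, tmp_path):
        path = write_vcf(
            tmp_path / "a.vcf",
            "1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
            "2\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n",
        )
        cohort = read_case_vcf(path, regions=[("1", 100, 200)])
        assert [v.chrom for v in cohort.variants] == ["1"]

    def test_depth_and_qd_are_read(self, tmp_path):
        path = write_vcf(
            tmp_path / "a.vcf",
            "1\t150\t.\tA\tG\t.\tPASS\tQD=3.5\tGT:DP\t0/1:8\t0/0:12\t0/0:10\n",
        )
        v = read_case_vcf(path).variants[0]
        assert v.mean_depth == pytest.approx(10.0)
        assert v.qd == pytest.approx(3.5)


class TestSplitMultiallelic:
    def _rec(self, genotypes, alts=("C", "T")):
        return RawRecord(
            chrom="1", pos=10, ref="A", alts=list(alts), genotypes=genotypes
        )

    def test_het_in_two_alts(self):
        out = split_multiallelic(self._rec([(1, 2)]))
        assert [int(v.dosages[0]) for v in out] == [1, 1]

    def test_hom_alt_biallelic(self):
        out = split_multiallelic(self._rec([(1, 1)], alts=("C",)))
        assert len(out) == 1
        assert int(out[0].dosages[0]) == 2

    def test_dosage_conservation_exhaustive(self):
        # every genotype pair over {0, 1, 2} at a triallelic site: the split
        # outputs' dosages must sum to the sample's non-reference allele count
        for g in itertools.product(range(3), repeat=2):
            out = split_multiallelic(self._rec([g]))
            total = sum(int(v.dosages[0]) for v in out)
            assert total == sum(1 for a in g if a > 0)

    def test_allele_index_out_of_range(self):
        with pytest.raises(VcfFormatError, match="1:10"):
            split_multiallelic(self._rec([(0, 3)]))

    def test_uncalled_sample_is_missing_in_every_output(self):
        out = split_multiallelic(self._rec([(-1, -1), (0, 1)]))
        for v in out:
            assert v.dosages[0] == MISSING
            assert v.dosages[1] >= 0


def _cohort_with_depths(depths_per_variant):
    variants = [
        CaseVariant(
            chrom="1", pos=100 + i, ref="A", alt="G",
            dosages=np.zeros(len(d), dtype=np.int8),
            depths=np.array(d),
        )
        for i, d in enumerate(depths_per_variant)
    ]
    n = len(depths_per_variant[0])
    return CaseCohort(samples=[f"S{i}" for i in range(n)], variants=variants)


class TestDepthFilter:
    def test_boundary_mean_kept(self):
        cohort = _cohort_with_depths([[8, 12, 10]])
        assert len(filter_mean_depth(cohort, 10).variants) == 1

    def test_low_mean_removed(self):
        cohort = _cohort_with_depths([[5, 6, 7]])
        assert filter_mean_depth(cohort, 10).variants == []

    def test_zero_threshold_is_identity(self):
        cohort = _cohort_with_depths([[5, 6, 7], [8, 12, 10]])
        assert len(filter_mean_depth(cohort, 0).variants) == 2

    def test_unassessable_depth_retained_with_warning(self, caplog):
        v = CaseVariant(chrom="1", pos=1, ref="A", alt="G",
                        dosages=np.zeros(2, dtype=np.int8))
        cohort = CaseCohort(samples=["a", "b"], variants=[v])
        with caplog.at_level("WARNING"):
            out = filter_mean_depth(cohort, 10)
        assert len(out.variants) == 1
        assert any("no depth" in r.message for r in caplog.records)

    def test_mean_over_samples_with_depth_only(self):
        # missing per-sample depths (-1) are excluded from the mean
        cohort = _cohort_with_depths([[9, 9, -1]])
        assert filter_mean_depth(cohort, 10).variants == []
        assert len(filter_mean_depth(cohort, 9).variants) == 1


class TestQdFilter:
    def _cohort(self, qd):
        v = CaseVariant(chrom="1", pos=1, ref="A", alt="G",
                        dosages=np.zeros(1, dtype=np.int8), qd=qd)
        return CaseCohort(samples=["a"], variants=[v])

    def test_boundary_strictly_greater(self):
        assert filter_qd(self._cohort(4.0), 4, enabled=True).variants == []
        assert len(filter_qd(self._cohort(4.01), 4, enabled=True).variants) == 1

    def test_disabled_is_identity(self):
        cohort = self._cohort(0.1)
        assert filter_qd(cohort, 4, enabled=False) is cohort

    def test_missing_qd_retained(self):
        assert len(filter_qd(self._cohort(None), 4, enabled=True).variants) == 1


@given(
    depths=st.lists(
        st.lists(st.integers(min_value=0, max_value=60), min_size=3, max_size=3),
        min_size=1,
        max_size=6,
    ),
    threshold=st.floats(min_value=0, max_value=30),
)
def test_filters_are_idempotent(depths, threshold):
    cohort = _cohort_with_depths(depths)
    once = filter_mean_depth(cohort, threshold)
    twice = filter_mean_depth(once, threshold)
    assert [v.key for v in once.variants] == [v.key for v in twice.variants]


def test_vcf_round_trip_preserves_dosages(tmp_path):
    rng = np.random.default_rng(0)
    variants = [
        CaseVariant(
            chrom="1", pos=100 + 7 * i, ref="A", alt="G",
            consequences={"missense_variant"},
            dosages=rng.integers(-1, 3, size=4).astype(np.int8),
            depths=rng.integers(5, 60, size=4),
            qd=round(float(rng.uniform(1, 20)), 2),
        )
        for i in range(10)
    ]
    cohort = CaseCohort(samples=["A", "B", "C", "D"], variants=variants)
    p1, p2 = tmp_path / "r1.vcf", tmp_path / "r2.vcf"
    write_case_vcf(cohort, p1)
    back = read_case_vcf(str(p1))
    assert back.samples == cohort.samples
    assert {v.key for v in back.variants} == {v.key for v in cohort.variants}
    b1, b2 = cohort.by_key(), back.by_key()
    for k in b1:
        np.testing.assert_array_equal(b1[k].dosages, b2[k].dosages)
        assert b1[k].consequences == b2[k].consequences
    # a second write/read cycle is byte-stable
    write_case_vcf(back, p2)
    assert p1.read_text() == p2.read_text()


def test_merge_cohorts_unions_samples_and_fills_missing():
    a = CaseCohort(
        samples=["A1"],
        variants=[CaseVariant(chrom="1", pos=5, ref="A", alt="G",
                              dosages=np.array([1], dtype=np.int8))],
    )
    b = CaseCohort(
        samples=["B1", "B2"],
        variants=[CaseVariant(chrom="1", pos=9, ref="C", alt="T",
                              dosages=np.array([0, 2], dtype=np.int8))],
    )
    merged = merge_cohorts(a, b)
    assert merged.samples == ["A1", "B1", "B2"]
    by = merged.by_key()
    np.testing.assert_array_equal(by["1:5:A:G"].dosages, [1, MISSING, MISSING])
    np.testing.assert_array_equal(by["1:9:C:T"].dosages, [MISSING, 0, 2])


def test_merge_rejects_shared_sample_ids():
    a = CaseCohort(samples=["X"], variants=[])
    b = CaseCohort(samples=["X"], variants=[])
    with pytest.raises(VcfFormatError):
        merge_cohorts(a, b)


def test_duplicate_records_dropped_on_read(tmp_path, caplog):
    path = write_vcf(
        tmp_path / "a.vcf",
        "1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
        "1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\n",
    )
    with caplog.at_level("WARNING"):
        cohort = read_case_vcf(path)
    assert len(cohort.variants) == 1
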