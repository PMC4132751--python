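import io as stringio

import pytest

from conftest import make_ref
from vntrcall.calling import (GenotypeCall, INFERRED, NOT_VNTR, OBSERVED,
                              UNCALLED, allele_support, call_locus, categorize,
                              check_mendelian, load_vcf_genotypes,
                              read_copy_delta, summary_report, write_vcf)
from vntrcall.profiles import TandemRepeat
from vntrcall.refset import ReferenceSet


def read_tr(array, pattern="ACGTACGTAT", read_id="r1", ordinal=1):
    return TandemRepeat(id=f"{read_id}:{ordinal}", pattern=pattern,
                        array=array, copies=len(array) / len(pattern),
                        left_flank="T" * 25, right_flank="G" * 25,
                        source=(read_id, ordinal))


class TestReadCopyDelta:
    def test_identical_array_is_zero(self):
        ref = make_ref()
        assert read_copy_delta(read_tr(ref.array), ref) == 0

    def test_single_copy_gain(self):
        ref = make_ref(n_copies=5)  # 10 nt pattern, 50 nt array
        assert read_copy_delta(read_tr(ref.pattern * 6), ref) == 1

    def test_rounding_toward_nearest_copy(self):
        ref = make_ref(n_copies=5)
        # read array 31 nt vs ref 50: round(-19/10) = -2
        assert read_copy_delta(read_tr(ref.array[:31]), ref) == -2

    def test_half_copy_rounds_away_from_zero(self):
        ref = make_ref(n_copies=5)
        assert read_copy_delta(read_tr(ref.array + ref.pattern[:5]), ref) == 1


class TestAlleleSupport:
    def test_minimum_two_reads_per_allele(self):
        assert allele_support([0, 0, 1]) == [(0, 2)]

    def test_two_supported_alleles(self):
        assert allele_support([1, 1, 0, 0]) == [(0, 2), (1, 2)]

    def test_single_read_gives_no_support(self):
        assert allele_support([-1]) == []


class TestCategorize:
    def test_reference_only_allele_is_not_vntr(self):
        call = categorize([(0, 5)], make_ref())
        assert call.category == NOT_VNTR
        assert not call.is_vntr

    def test_single_nonzero_allele_is_inferred(self):
        call = categorize([(1, 3)], make_ref())
        assert call.category == INFERRED

    def test_two_alleles_with_reference_is_observed_same_diff(self):
        call = categorize([(-1, 2), (0, 4)], make_ref())
        assert call.category == OBSERVED
        assert call.subtype() == "Same/Diff"

    def test_two_nonreference_alleles_is_diff_diff(self):
        call = categorize([(-1, 2), (2, 2)], make_ref())
        assert call.subtype() == "Diff/Diff"

    def test_more_than_two_alleles_flagged_multi_allelic(self):
        call = categorize([(-1, 2), (0, 3), (1, 2)], make_ref())
        assert call.category == OBSERVED
        assert call.multi_allelic

    def test_no_supported_alleles_uncalled(self):
        call = categorize([], make_ref())
        assert call.category == UNCALLED

    def test_call_locus_enforces_min_support(self):
        ref = make_ref(n_copies=5)
        reads = [read_tr(ref.pattern * 6, read_id=f"r{i}") for i in range(2)]
        reads.append(read_tr(ref.array, read_id="r9"))
        call = call_locus(ref, reads)
        assert call.supported_alleles == [(1, 2)]
        assert call.category == INFERRED


class TestVcf:
    def _write(self, calls, refs):
        refset = ReferenceSet(repeats=refs)
        vntr, alle = stringio.StringIO(), stringio.StringIO()
        write_vcf(calls, refset, "s1", vntr, alle)
        return vntr.getvalue(), alle.getvalue()

    def test_not_vntr_only_in_all_file_with_gt_00(self):
        ref = make_ref()
        vntr, alle = self._write([categorize([(0, 4)], ref)], [ref])
        assert ref.id not in vntr
        assert ref.id in alle
        assert alle.strip().splitlines()[-1].endswith("GT\t0/0")

    def test_inferred_vntr_gt_homozygous_alt(self):
        ref = make_ref()
        vntr, _ = self._write([categorize([(1, 3)], ref)], [ref])
        assert vntr.strip().splitlines()[-1].endswith("GT\t1/1")

    def test_observed_same_diff_gt_het(self):
        ref = make_ref()
        vntr, _ = self._write([categorize([(-1, 2), (0, 2)], ref)], [ref])
        assert vntr.strip().splitlines()[-1].endswith("GT\t0/1")

    def test_alt_reconstruction_by_copy_arithmetic(self):
        ref = make_ref(n_copies=5)
        vntr, _ = self._write([categorize([(1, 3)], ref)], [ref])
        line = vntr.strip().splitlines()[-1].split("\t")
        anchor = ref.left_flank[-1]
        assert line[3] == anchor + ref.array
        assert line[4] == anchor + ref.array + ref.pattern

    def test_roundtrip_recovers_deltas_and_support(self, tmp_path):
        refs = [make_ref("refA", start=1000),
                make_ref("refB", start=5000, pattern="GATTACAGG")]
        calls = [categorize([(0, 3), (2, 2)], refs[0]),
                 categorize([(-1, 4)], refs[1])]
        path = tmp_path / "all.vcf"
        with open(tmp_path / "v.vcf", "w") as v, open(path, "w") as a:
            write_vcf(calls, ReferenceSet(repeats=refs), "s1", v, a)
        back = load_vcf_genotypes(str(path))
        assert back["refA"] == ([0, 2], [3, 2])
        assert back["refB"] == ([-1], [4])

    def test_emitted_vcf_parses_with_cyvcf2(self, tmp_path):
        import cyvcf2
        refs = [make_ref("refA", start=1000)]
        calls = [categorize([(0, 3), (2, 2)], refs[0])]
        path = str(tmp_path / "all.vcf")
        with open(tmp_path / "v.vcf", "w") as v, open(path, "w") as a:
            write_vcf(calls, ReferenceSet(repeats=refs), "s1", v, a)
        records = list(cyvcf2.VCF(path))
        assert len(records) == 1
        rec = records[0]
        assert rec.ID == "refA"
        assert rec.INFO["RU"] == refs[0].pattern
        assert rec.genotypes[0][:2] == [0, 1]


def biallelic(deltas):
    return GenotypeCall(ref_id="x", ref_copies=5,
                        supported_alleles=[(d, 2) for d in deltas],
                        category=OBSERVED if len(deltas) > 1 else NOT_VNTR)


class TestMendelian:
    def _calls(self, genotypes):
        return {rid: GenotypeCall(ref_id=rid, ref_copies=5,
                                  supported_alleles=[(d, 2) for d in sorted(g)],
                                  category=OBSERVED)
                for rid, g in genotypes.items()}

    def test_one_allele_from_each_parent_consistent(self):
        rep = check_mendelian(self._calls({"L1": {1, -1}}),
                              self._calls({"L1": {0, 1}}),
                              self._calls({"L1": {0, -1}}))
        assert rep.n_common == 1
        assert rep.n_inconsistent == 0
        assert rep.n_all_diff == 1

    def test_child_alleles_absent_from_parents_inconsistent(self):
        rep = check_mendelian(self._calls({"L1": {-1, 2}}),
                              self._calls({"L1": {0, 1}}),
                              self._calls({"L1": {0, 1}}))
        assert rep.inconsistent == ["L1"]

    def test_identical_trio_genotypes_consistent_not_diff(self):
        rep = check_mendelian(self._calls({"L1": {0, 1}}),
                              self._calls({"L1": {0, 1}}),
                              self._calls({"L1": {0, 1}}))
        assert rep.n_common == 1
        assert rep.n_all_diff == 0
        assert rep.n_inconsistent == 0

    def test_locus_missing_in_one_sample_excluded(self):
        rep = check_mendelian(self._calls({"L1": {0, 1}}),
                              self._calls({"L1": {0, 1}, "L2": {0, 1}}),
                              self._calls({"L2": {0, 1}}))
        assert rep.n_common == 0


class TestSummaryReport:
    def test_empty_run_all_zero(self):
        refset = ReferenceSet(repeats=[])
        counts = summary_report(refset, 0, {}, [])
        assert all(v == 0 for v in counts.values())

    def test_counts_reflect_calls(self):
        refs = [make_ref(f"ref{i}", start=1000 * (i + 1)) for i in range(4)]
        refset = ReferenceSet(repeats=refs)
        calls = [categorize([(0, 5)], refs[0]),
                 categorize([(1, 2)], refs[1]),
                 categorize([(0, 2), (1, 2)], refs[2]),
                 categorize([], refs[3])]
        counts = summary_report(refset, 40, {"ref0": 5, "ref1": 2, "ref2": 4,
                                             "ref3": 1}, calls)
        assert counts["refs_total"] == 4
        assert counts["refs_mapped_ge1"] == 4
        assert counts["refs_mapped_ge2"] == 3
        assert counts["refs_with_support"] == 3
        assert counts["not_vntr"] == 1
        assert counts["inferred_vntr"] == 1
        assert counts["observed_vntr"] == 1
        assert counts["observed_same_diff"] == 1
        assert counts["vntr_total"] == 2
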