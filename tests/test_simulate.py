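import numpy as np
import pytest

from vntrcall.profiles import revcomp
from vntrcall.simulate import (LengthModel, add_sequencing_errors,
                               annotate_ground_truth, apply_454_errors,
                               apply_illumina_errors, expected_spanning,
                               make_trio, plant_reference, plant_vntrs,
                               simulate_reads)


class TestPlantReference:
    def test_zero_loci_gives_pure_random_genome(self):
        genome, refset = plant_reference(genome_len=10_000, n_loci=0, seed=5)
        assert len(genome["chr1"]) == 10_000
        assert len(refset) == 0

    def test_array_present_verbatim_at_coordinates(self):
        genome, refset = plant_reference(genome_len=50_000, n_loci=5, seed=5)
        for tr in refset.repeats:
            assert genome[tr.chrom][tr.start:tr.end] == tr.array
            assert tr.array == "".join(tr.copy_units)
            assert genome[tr.chrom][tr.start - len(tr.left_flank):tr.start] \
                == tr.left_flank

    def test_deterministic_under_seed(self):
        g1, r1 = plant_reference(genome_len=50_000, n_loci=20, seed=9)
        g2, r2 = plant_reference(genome_len=50_000, n_loci=20, seed=9)
        assert g1 == g2
        assert [(t.id, t.start, t.array) for t in r1.repeats] == \
               [(t.id, t.start, t.array) for t in r2.repeats]

    def test_minisatellite_constraints_respected(self):
        genome, refset = plant_reference(genome_len=100_000, n_loci=30, seed=6)
        for tr in refset.repeats:
            assert tr.pattern_len >= 7
            assert len(tr.copy_units) >= 2
            assert tr.array_len <= 120

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            plant_reference(genome_len=2_000, n_loci=50, seed=1)


class TestPlantVntrs:
    def test_fraction_zero_keeps_haplotypes_identical(self, small_refset):
        genome, refset = small_refset
        ds = plant_vntrs(refset, genome, fraction=0.0, seed=4)
        assert ds.haplotypes[0].genome == ds.haplotypes[1].genome
        assert all(t.zygosity == "unmodified" for t in ds.truth)

    def test_copy_arithmetic(self, small_refset):
        genome, refset = small_refset
        ds = plant_vntrs(refset, genome, n_variants=8, seed=4)
        for t in ds.truth:
            if t.zygosity == "unmodified":
                continue
            ref = refset.by_id[t.ref_id]
            placed = ds.haplotypes[1].loci[t.ref_id]
            assert len(placed.units) == len(ref.copy_units) + t.delta_b
            assert t.delta_b in (-2, -1, 1, 2)
            assert len(placed.units) >= 2

    def test_ceiling_fraction_selects_expected_count(self, small_refset):
        genome, refset = small_refset  # 30 loci; 0.1 -> 3 variants
        ds = plant_vntrs(refset, genome, fraction=0.1, seed=4)
        assert sum(1 for t in ds.truth if t.zygosity != "unmodified") == 3

    def test_heterozygous_mode_modifies_one_haplotype(self, small_refset):
        genome, refset = small_refset
        ds = plant_vntrs(refset, genome, n_variants=5,
                         zygosity="heterozygous", seed=4)
        for t in ds.truth:
            if t.zygosity == "heterozygous":
                assert t.delta_a == 0 and t.delta_b != 0
        assert ds.haplotypes[0].genome == genome

    def test_variant_arrays_spliced_into_haplotype(self, small_refset):
        genome, refset = small_refset
        ds = plant_vntrs(refset, genome, n_variants=5, seed=4)
        hap = ds.haplotypes[1]
        for rid, placed in hap.loci.items():
            assert hap.genome[placed.chrom][placed.start:placed.end] == \
                "".join(placed.units)


class TestSimulateReads:
    def test_fixed_length_reads_match_haplotype(self, small_refset):
        genome, refset = small_refset
        ds = plant_vntrs(refset, genome, fraction=0.0, seed=4)
        reads = simulate_reads(ds.haplotypes, 5, LengthModel("fixed", length=100),
                               seed=8)
        for r in reads:
            hap = next(h for h in ds.haplotypes if h.name == r.haplotype)
            segment = hap.genome[r.chrom][r.start:r.start + r.length]
            assert r.seq == (segment if r.strand == "+" else revcomp(segment))
            assert len(r.seq) == 100

    def test_normal_length_model_mean(self, small_refset):
        genome, refset = small_refset
        ds = plant_vntrs(refset, genome, fraction=0.0, seed=4)
        reads = simulate_reads(ds.haplotypes, 10_000,
                               LengthModel("normal", mean=261, sd=27), seed=8)
        lengths = np.array([r.length for r in reads])
        assert abs(lengths.mean() - 261) < 3 * 27 / np.sqrt(len(lengths))

    def test_same_seed_same_reads(self, small_refset):
        genome, refset = small_refset
        ds = plant_vntrs(refset, genome, fraction=0.0, seed=4)
        r1 = simulate_reads(ds.haplotypes, 50, LengthModel("fixed"), seed=8)
        r2 = simulate_reads(ds.haplotypes, 50, LengthModel("fixed"), seed=8)
        assert [(x.id, x.seq, x.start) for x in r1] == \
               [(x.id, x.seq, x.start) for x in r2]


class TestErrorModels:
    def test_zero_rates_leave_read_unchanged(self):
        rng = np.random.default_rng(0)
        seq = "ACGTAACCGGTT" * 10
        out, cmap = apply_454_errors(seq, rng, rates=lambda n: (0, 0, 0))
        assert out == seq
        assert cmap == list(range(len(seq) + 1))
        out, cmap = apply_illumina_errors(seq, rng, sub_curve=lambda p, n: 0.0,
                                          indel_rate=0.0)
        assert out == seq

    def test_forced_overcall_extends_homopolymer(self):
        rng = np.random.default_rng(0)
        out, cmap = apply_454_errors(
            "AAAC", rng, rates=lambda n: (1.0, 0.0, 0.0) if n >= 3 else (0, 0, 0))
        assert out == "AAAAC"

    def test_forced_substitution_changes_every_base(self):
        rng = np.random.default_rng(0)
        seq = "ACGTACGTAC"
        out, _ = apply_illumina_errors(seq, rng, sub_curve=lambda p, n: 1.0,
                                       indel_rate=0.0)
        assert len(out) == len(seq)
        assert all(a != b for a, b in zip(seq, out))

    def test_substitution_rate_matches_curve(self):
        rng = np.random.default_rng(1)
        rate = 0.02
        n, length = 3000, 100
        seq = "ACGT" * 25
        changed = 0
        for _ in range(n):
            out, _ = apply_illumina_errors(seq, rng,
                                           sub_curve=lambda p, L: rate,
                                           indel_rate=0.0)
            changed += sum(a != b for a, b in zip(seq, out))
        total = n * length
        expect = total * rate
        sd = np.sqrt(total * rate * (1 - rate))
        assert abs(changed - expect) < 3 * sd

    def test_coordinate_map_tracks_indels(self):
        rng = np.random.default_rng(0)
        seq = "AAAACGT"
        out, cmap = apply_454_errors(
            seq, rng, rates=lambda n: (0.0, 1.0, 0.0) if n >= 4 else (0, 0, 0))
        assert out == "AAACGT"
        assert cmap[4] == 3  # boundary after the homopolymer shifted left
        assert cmap[7] == 6


class TestAnnotation:
    def test_spanning_read_annotated_with_flanks(self, small_dataset):
        refset, dataset, annotations, origins = small_dataset
        assert annotations
        for tr in annotations[:50]:
            assert len(tr.left_flank) >= 20
            assert len(tr.right_flank) >= 20
            rid = origins[tr.source]
            ref = refset.by_id[rid]
            assert tr.pattern in (ref.pattern, revcomp(ref.pattern))

    def test_annotated_array_matches_haplotype_allele(self, small_dataset):
        refset, dataset, annotations, origins = small_dataset
        hap_by_name = {h.name: h for h in dataset.haplotypes}
        read_by_id = {r.id: r for r in dataset.reads}
        for tr in annotations[:50]:
            read = read_by_id[tr.source[0]]
            placed = hap_by_name[read.haplotype].loci[origins[tr.source]]
            expect = "".join(placed.units)
            assert tr.array in (expect, revcomp(expect))

    def test_read_inside_array_not_annotated(self, small_refset):
        genome, refset = small_refset
        ds = plant_vntrs(refset, genome, fraction=0.0, seed=4)
        tr = max(refset.repeats, key=lambda t: t.array_len)
        from vntrcall.simulate import SimRead
        hap = ds.haplotypes[0]
        placed = hap.loci[tr.id]
        inner = SimRead(id="x", haplotype=hap.name, chrom=placed.chrom,
                        start=placed.start, length=placed.array_len,
                        strand="+",
                        seq=hap.genome[placed.chrom][placed.start:placed.end])
        ann, origins = annotate_ground_truth([inner], ds.haplotypes, refset)
        assert ann == []

    def test_read_spanning_two_loci_gets_two_ordinals(self, small_refset):
        genome, refset = small_refset
        ds = plant_vntrs(refset, genome, fraction=0.0, seed=4)
        hap = ds.haplotypes[0]
        loci = sorted(hap.loci.values(), key=lambda p: p.start)
        a, b = loci[0], loci[1]
        from vntrcall.simulate import SimRead
        start = a.start - 30
        length = b.end + 30 - start
        big = SimRead(id="x", haplotype=hap.name, chrom=a.chrom, start=start,
                      length=length, strand="+",
                      seq=hap.genome[a.chrom][start:start + length])
        ann, origins = annotate_ground_truth([big], ds.haplotypes, refset)
        assert [t.source for t in ann] == [("x", 1), ("x", 2)]


class TestExpectedSpanning:
    def test_cannot_span_when_array_plus_flanks_exceed_read(self):
        assert expected_spanning(100, 100, 20, 10_000, 1000) == 0.0

    def test_single_valid_position(self):
        # A + 2f = L -> exactly one valid start
        p = expected_spanning(60, 100, 20, 10_000, 1)
        assert p == pytest.approx(1 / (10_000 - 100 + 1))

    def test_closed_form_example(self):
        val = expected_spanning(20, 100, 20, 10_000, 1000, k=1)
        expect = 1 - (1 - 41 / 9901) ** 1000
        assert val == pytest.approx(expect, rel=1e-9)
        assert val == pytest.approx(0.9842, abs=5e-4)


class TestTrio:
    def test_child_alleles_inherited_from_parents(self, small_refset):
        genome, refset = small_refset
        trio = make_trio(refset, genome, seed=3, n_variants=10)
        mother = {t.ref_id: {t.delta_a, t.delta_b} for t in trio["mother"].truth}
        father = {t.ref_id: {t.delta_a, t.delta_b} for t in trio["father"].truth}
        for t in trio["child"].truth:
            assert t.delta_a in mother[t.ref_id]
            assert t.delta_b in father[t.ref_id]

    def test_deterministic(self, small_refset):
        genome, refset = small_refset
        t1 = make_trio(refset, genome, seed=3, n_variants=10)
        t2 = make_trio(refset, genome, seed=3, n_variants=10)
        for person in t1:
            assert [(x.ref_id, x.delta_a, x.delta_b) for x in t1[person].truth] \
                == [(x.ref_id, x.delta_a, x.delta_b) for x in t2[person].truth]
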