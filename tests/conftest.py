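import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from vntrcall.profiles import TandemRepeat
from vntrcall.simulate import (LengthModel, annotate_ground_truth,
                               plant_reference, plant_vntrs, simulate_reads)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_refset():
    """30 planted loci on a 100 kb genome."""
    genome, refset = plant_reference(genome_len=100_000, n_loci=30, seed=1)
    return genome, refset


@pytest.fixture(scope="session")
def small_dataset(small_refset):
    """Homozygous dataset with 5 variant loci, exact 250 nt reads."""
    genome, refset = small_refset
    dataset = plant_vntrs(refset, genome, zygosity="homozygous", seed=2,
                          n_variants=5)
    reads = simulate_reads(dataset.haplotypes, 8000,
                           LengthModel(kind="fixed", length=250), seed=3)
    dataset.reads = reads
    annotations, origins = annotate_ground_truth(reads, dataset.haplotypes,
                                                 refset)
    return refset, dataset, annotations, origins


def make_ref(ref_id="refA", pattern="ACGTACGTAT", n_copies=5, chrom="chr1",
             start=1000, left="T" * 60, right="G" * 60) -> TandemRepeat:
    array = pattern * n_copies
    return TandemRepeat(id=ref_id, pattern=pattern, array=array,
                        copies=float(n_copies), chrom=chrom, start=start,
                        end=start + len(array), left_flank=left,
                        right_flank=right,
                        copy_units=[pattern] * n_copies)
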