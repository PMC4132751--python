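# vntrcall

Genotyping of **minisatellite VNTRs** (variable number of tandem repeat
loci, pattern ≥ 7 nt) from whole-genome sequencing reads that *span* the
repeat array.

A tandem repeat locus is an array of adjacent, approximate copies of a
pattern; a VNTR is a locus whose copy number differs between genomes.
VNTRs are indels with respect to the reference, but because the inserted
or deleted unit is itself repetitive (and copies may be inexact and
rearranged), conventional indel callers handle them poorly.  `vntrcall`
takes the approach of mapping *TR-containing reads* to a *reference TR
set* using alignment of repeat **profiles** and of flanking sequence,
then calling copy-number alleles from the mapped reads.  It is intended
for users with (a) a reference TR table (e.g. from Tandem Repeats
Finder), (b) reads, and (c) per-read TR annotations — or, for
validation, the bundled diploid read simulator, which supplies all
three.

## Method

Each TR array is summarized as a normalized profile `P = C1 C2 … Ck`,
one column per position of a multiple alignment of its pattern copies.
A column `C = (n_A, n_C, n_G, n_T, n_-)` holds nucleotide and gap counts
rescaled to sum exactly 10 and snapped to the nearest of the 1001 legal
integer compositions (Euclidean distance; N's are ignored).

Candidate read-TR/reference pairings come from a spaced-seed index over
the consensus patterns (both orientations, cyclically extended so
rotated patterns share seeds), pre-filtered by longest common
subsequence of the consensus patterns: LCS ≥ 85% of the shorter pattern
and length difference ≤ 10%.  Surviving pairs are confirmed by two
alignments:

* **Profile alignment.**  Global alignment of the two column sequences
  (banded DP, all cyclic rotations, both orientations) minimizing the
  weighted distance

  ```
  WD(P1,P2) = Σ_i E_i(V,W) · Weight_i
  Weight_i  = min(10, 20 − (gaps(V) + gaps(W)))
  WS(P1,P2) = 100 − [ WD / (255 · Σ_i Weight_i) ] · 100
  ```

  where `E_i` is the Euclidean distance between matched columns scaled
  so the worst case maps to 255, and columns aligned to gaps are paired
  with the all-gap column `(0,0,0,0,10)` so indel-dominated positions
  are down-weighted.  A pairing needs `WS ≥ 88`.

* **Flank alignment.**  Unit-cost edit distance (bit-parallel) of the
  sequences adjacent to the arrays, with ≤ 10% errors relative to the
  combined read flank lengths (read flanks ≥ 20 nt required, truncated
  to the array-proximal 50 nt by default).

Mapping then uses two-list best-score selection: pairs ranked by WS and
by flank error rate; a read-TR maps to a reference only if it is best in
*both* lists, ties are removed, reads touching ≥ 3 references (or 2 that
are too far apart for the read length) are discarded, and PCR duplicates
(length difference ≤ 2 nt, LCS ≥ shorter − 3) are collapsed.  An allele
(keyed by integer copy delta vs the reference) is **supported** by ≥ 2
mapped reads; loci are called *not a VNTR* (single allele, delta 0),
*inferred VNTR* (single non-reference allele) or *observed VNTR* (two
alleles).  References confusable with another family member under
profile comparison plus a one-sided 50 nt flank test are flagged
*indistinguishable*, since calls there are unreliable.

## Worked example

Simulate a 200 kb diploid genome with 50 planted loci and 5 homozygous
variant loci, genotype it, and score the run against the planted truth:

```
$ vntrcall simulate --genome-len 200000 --n-loci 50 --n-variants 5 \
      --coverage 20 --seed 42 -o demo/sim
wrote 16000 reads, 593 read-TRs, 5 variant loci to demo/sim

$ vntrcall run --refs demo/sim/reference.tsv --reads demo/sim/reads.fastq \
      --annotations demo/sim/read_trs.tsv -o demo/out
called 4 VNTRs (4 inferred, 0 observed)

$ vntrcall evaluate --outdir demo/sim
read_mapping_sensitivity        1.0
read_mapping_precision          1.0
unmodified_specificity          1.0
homozygous_sensitivity          1.0
vntr_ppv                        1.0
n_genotypable_homozygous        4
```

Every read-TR mapped to its source locus; 4 of the 5 planted variants
had at least two spanning reads (the accuracy denominator counts only
such *genotypable* loci — the fifth had insufficient spanning coverage
at 20×) and all 4 were recovered with no false positives.  `demo/out`
holds two VCF 4.2 files — `sample.vntr.vcf` (VNTR calls only) and
`sample.all.vcf` (every locus with a supported allele) — plus a mapping
table and a stage-by-stage summary.  In the VCF, POS anchors the base
before the array, INFO carries the repeat unit (`RU`), reference copy
number (`RC`), per-allele copy deltas (`CD`) and read support (`RS`),
and GT is 0/0, 1/1 or 0/1 for reference, inferred and observed calls.

Other subcommands: `build-refset` (redundancy elimination of overlapping
reference annotations), `classify-indistinguishable`, and `mendelian`
(trio consistency over bi-allelic loci).

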