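# Methods

This note documents the model and procedure implemented by `vntrcall`,
the parameters that matter, the design choices made where the design was
genuinely open, what the synthetic-data generator does and does not
emulate, and known limitations.

## Profile representation

A tandem array is represented by an ordered sequence of *normalized
columns*, one per column of a multiple alignment of its pattern copies.
Raw per-column counts over {A, C, G, T, gap} are rescaled proportionally
to sum 10 and snapped to the nearest of the 1001 integer compositions of
10 into 5 parts (Euclidean distance).  The snap is computed by
largest-remainder apportionment, which is provably the L2-closest
composition; remainder ties break toward the lowest symbol index
(A < C < G < T < gap), making the operation deterministic and
order-independent.  Columns containing only N are rejected; N's
otherwise contribute nothing.

The multiple alignment of copies is a *star alignment*: each copy is
globally aligned to the consensus pattern by unit-cost edit distance
(edlib supplies the traceback), and counts are accumulated per
consensus-anchored column.  Insertions relative to the consensus are
retained as extra columns only at gap slots where at least half the
copies carry a base; rarer insertions are dropped.  For the near-exact
copies typical of minisatellite arrays this choice is inconsequential,
but it keeps column counts stable for noisy arrays.  Arrays are split
into copies greedily: the prefix of the remaining array with the
smallest edit distance to the consensus (length within ±20% of the
pattern length) becomes the next copy; a trailing partial copy is kept
and simply contributes gap counts in its missing columns.

## Alignment scores

**Column distance.**  Euclidean distance between two 5-vectors, scaled
so the worst case (two disjoint pure columns, distance √200) maps to
255, rounded half-up.  The integer quantization makes the WS
denominator `255 · ΣWeight` exact.

**Position weight.**  `min(10, 20 − gaps(V) − gaps(W))`, floored at 0.
A column aligned to a gap is paired with the constant all-gap column
`(0,0,0,0,10)`, so pure indel positions carry weight ≤ 10 − gaps(V) and
heavily gapped columns contribute little.

**Profile alignment.**  Global DP over the two column sequences
minimizing `WD = Σ distance·weight`; among equal-cost paths the larger
accumulated weight wins (then diagonal before vertical before
horizontal), making the result deterministic.  The DP runs in a
diagonal band of half-width `|k1 − k2| + band` (default `band = 5`,
config-exposed); a band that cannot connect the corners is widened
automatically with a logged warning.  All cyclic rotations of the read
profile and both orientations are evaluated — correctness over speed at
minisatellite scale — and the rotation maximizing
`WS = 100 − WD/(255·ΣWeight)·100` is kept.  WS is bounded in [0, 100]
because every path step satisfies `cost ≤ 255·weight`.  The kernel is
JIT-compiled with numba when available, with an identical pure-Python
fallback.  The acceptance threshold is WS ≥ 88 (inclusive), compared in
exact rational arithmetic.

**Flank alignment.**  Unit-cost edit distance via the Myers bit-parallel
algorithm (arbitrary-precision integers as the bit vector, so no
word-boundary blocking).  On each side the shorter of read and
reference flank is located within the longer by approximate substring
matching (the search variant of the same algorithm: free leading and
trailing gaps in the longer sequence).  This forgives overhangs at
contig edges and small array-boundary disagreements between the read
annotator and the reference table.  Error rate = (left + right
errors) / (combined read flank length); threshold ≤ 10%, inclusive,
exact-rational comparison.  Read flanks must be ≥ 20 nt and are
truncated to the array-proximal 50 nt by default (configurable to
unrestricted); reference flanks use 50 nt.

## Candidate generation

A spaced-seed index (default shape `11011011`, span 8, weight 6,
configurable) over the reference consensus patterns and their reverse
complements, each cyclically extended by span − 1 characters so all
phase shifts of a pattern share keys.  One shared seed suffices
(`min_seed_hits = 1`): the seed stage is purely a cheap pre-filter, and
the LCS gate does the real discrimination.  The LCS filter compares the
read consensus against the reference consensus *doubled* (capped at the
shorter original length) rather than trying all rotations explicitly;
this is cheaper and slightly more permissive than true cyclic LCS,
which is acceptable for a pre-filter that is followed by the WS gate.
Thresholds (LCS ≥ 85% of shorter, length difference ≤ 10% of shorter)
are compared in exact rational arithmetic; the shorter-pattern base for
the length rule is the stricter reading and consistent with the LCS
rule's base.

## Mapping and deduplication

Pairs passing all filters are ranked twice: by WS and by flank error
rate (lower is better; scores compare as exact rationals, never by
float tolerance).  In each list a read-TR keeps its best reference(s)
including ties, and each reference keeps the best read-TR among several
from the same read (ties → highest ordinal).  The two lists are merged
by intersection; a read-TR whose two best sets still contain ≥ 2
references is removed as a tie, and one whose sets do not intersect is
removed as a score conflict.  Whole reads are discarded when their TRs
map to ≥ 3 references, or to 2 references on different chromosomes or
whose combined genomic span exceeds the read length.  PCR duplicates
(length difference ≤ 2 nt and LCS ≥ shorter − 3) among reads mapped to
one reference are clustered transitively; the longest read survives
(ties → lexicographically smallest id) as it carries the most flank
information.

## Genotyping

Alleles are keyed by the integer copy delta
`round((read array − reference array) / pattern length)`, rounded half
away from zero — robust to fractional copy reporting and small
annotation jitter.  An allele needs ≥ 2 supporting reads.  One
supported allele equal to the reference → not a VNTR; one non-reference
allele → inferred VNTR (genotyped 1/1, trusting the reference); two
alleles → observed VNTR (0/1 when one allele is the reference, 1/2
otherwise).  More than two supported alleles is biologically
unexpected but observed in real data; all alleles are emitted with a
`MULTI` flag and the two best-supported form the genotype.  VCF ALT
sequences are reconstructed by appending or trimming whole consensus
copies at the array's 3' end.

## Reference curation

Redundancy elimination removes, from any pair of repeats overlapping by
more than 50% of the *shorter* array (strict inequality — the natural
reading of "more than 50% of their length"), the shorter-array repeat;
ties keep the shorter period, then the lower start coordinate.  Applied
iteratively in deterministic (chromosome, start) order until stable.

Indistinguishable classification self-maps the reference set through
the same seed/LCS/WS cascade, with the flank test weakened to *either*
side alone at exactly 50 nt and ≤ 10% errors (≤ 5).  Any non-self pass
flags the query.  The classification is per-query: A passing against B
flags A; B is flagged only by its own comparisons.

## The simulator

The generator is the package's validation instrument; its defaults
define the study conditions for the closed-loop tests.

* **Genome.**  Uniform random background (1 Mb default) with 300
  planted loci: random patterns 7–60 nt with ≥ 2 distinct bases, copy
  number uniform in 2–5, resampled until the array is ≤ 120 nt.  The
  cap reflects the method's domain: a spanning-read caller can only
  genotype arrays ≤ read length − 2·min flank (210 nt for 250 nt
  reads), and the cap keeps planted loci inside that regime with
  margin.  Loci are ≥ 100 nt apart.  Per-copy point mutations are
  supported (default off).
* **Variants.**  A fraction (default 0.5%, or an explicit count) of
  loci get a delta drawn from {−2, −1, +1, +2} by duplicating or
  removing randomly chosen existing copies; removals leaving < 2 copies
  are redrawn (a 1-copy remnant would not be annotated as a repeat).
  Homozygous mode modifies both haplotypes; heterozygous mode modifies
  one, and reads are drawn equally from both.
* **Reads.**  Uniform placement on a uniformly chosen haplotype,
  uniform strand; lengths fixed (250 nt default; 100 nt Illumina-like)
  or normal (mean 261 nt, sd 27 nt, truncated at 30 nt, 454-like) —
  numpy's normal sampler is used.
* **Errors.**  454 model: per-maximal-homopolymer overcall/undercall
  probabilities growing linearly from 0.2%/0.1% at run length 2 to
  8%/5% at length ≥ 8; length-1 runs use half the length-2 indel rates
  and a 0.05% substitution rate.  Illumina model: per-base substitution
  ramping 0.1% → 1% across the read, single-base indels at 0.01%.  The
  empirical rate tables behind published 454/Illumina characterizations
  are not reproduced here; all rates are config-overridable.  Error
  application returns a boundary map so ground-truth annotations carry
  coordinates mapped through the errors.
* **Annotations.**  A read spanning a planted array with ≥ 20 nt on
  both sides (after errors) yields a read-TR with the haplotype-correct
  array and the source consensus (reverse-complemented for minus-strand
  reads).  This replaces a tandem repeat finder on reads, so the
  closed-loop tests do **not** measure annotator failures — on real
  data, TR finders miss short or error-laden arrays, which lowers
  sensitivity (substantially for short erroneous reads).  Other real
  features not emulated: flanks can be repetitive or low-complexity,
  repeat families create indistinguishable references, coverage is
  non-uniform, and PCR duplicates are genuinely clonal rather than
  coincidental.  Passing tests demonstrate the pipeline's correctness
  and its behavior under the stated error models, not field accuracy.
* **Trios.**  One alternate allele per selected locus; each parent
  carries two independent draws from {reference, alternate}; the child
  inherits one uniformly chosen allele per parent.  Alternate arrays
  are built once and shared, so transmission is identical by descent.

`expected_spanning` gives the closed-form probability that ≥ k of N
uniformly placed fixed-length reads span an array with both flanks:
valid starts `v = max(0, L − A − 2f + 1)`, per-read probability
`p = v/(G − L + 1)`, Binomial(N, p) upper tail.

## Evaluation denominators

Accuracy on simulated data is reported over *genotypable* loci: those
with ≥ 2 ground-truth spanning read-TRs (per haplotype class, for
heterozygous loci — both the modified and unmodified chromosome must be
spanned twice).  A locus without two spanning reads cannot be genotyped
by any spanning-read method at any accuracy, so including it would
measure coverage, not the caller.  Read-mapping sensitivity excludes
reads removed as PCR duplicates (their removal is by design, not a
mapping failure).

## Problem sizes and numerical choices

The closed-loop tests use a 1 Mb genome, 300 loci, 15 variant loci and
coverage 20 (80,000 reads of 250 nt); the trio test uses 300 kb, 100
loci, 40 variant loci and three read sets of 24,000 reads.  These sizes
give every stage of the pipeline thousands of read-TRs while keeping a
full run in tens of seconds.  All randomness flows from explicit seeds;
identical seeds give byte-identical outputs.  Exact rational arithmetic
is used wherever a threshold or tie is decided (WS, flank rates, LCS
fractions), so no decision depends on float rounding.

## Known limitations

* Gap costs are linear (unit per column against the all-gap column);
  no affine gap model.
* Base qualities are ignored throughout.
* Alleles differing by less than half a pattern copy collapse to the
  same integer delta.
* The LCS rotation handling (doubled pattern) can admit pairs a true
  cyclic-rotation LCS would reject; the WS gate compensates.
* The one-sided flank rule for indistinguishable classification uses
  exactly 50 nt flanks; references closer than 50 nt to a contig edge
  are compared on the available sequence.
* Reads are treated as single-end; pair information is unused because
  only spanning reads inform copy number.
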