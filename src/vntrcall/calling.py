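"""Genotyping of reference TRs from mapped, deduplicated reads.

An allele is keyed by its integer copy-number difference ("delta") from
the reference array.  An allele has *support* when at least two mapped
reads carry it.  Loci are then categorized:

* one supported allele, delta 0      -> not a VNTR
* one supported allele, delta != 0   -> inferred VNTR (reference trusted)
* two or more supported alleles      -> observed VNTR (Same/Diff when one
  allele equals the reference, Diff/Diff otherwise; more than two
  supported alleles is flagged multi-allelic)

Calls are emitted as two VCF 4.2 files: one restricted to VNTRs, one
with every locus that has at least one supported allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

from .profiles import TandemRepeat
from .refset import ReferenceSet, SINGLETON

NOT_VNTR = "not-VNTR"
INFERRED = "inferred-VNTR"
OBSERVED = "observed-VNTR"
UNCALLED = "uncalled"

MIN_SUPPORT_DEFAULT = 2


@dataclass
class GenotypeCall:
    """Supported copy-number alleles at one reference locus."""

    ref_id: str
    ref_copies: int
    supported_alleles: list[tuple[int, int]]  # (copy delta, read support)
    category: str
    multi_allelic: bool = False
    ref_category: str = SINGLETON

    @property
    def deltas(self) -> set[int]:
        return {d for d, _ in self.supported_alleles}

    @property
    def is_vntr(self) -> bool:
        return self.category in (INFERRED, OBSERVED)

    def subtype(self) -> Optional[str]:
        """Observed-VNTR subtype: Same/Diff when the reference allele is
        one of the two supported alleles, Diff/Diff otherwise."""
        if self.category != OBSERVED:
            return None
        return "Same/Diff" if 0 in self.deltas else "Diff/Diff"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def read_copy_delta(read_tr: TandemRepeat, ref: TandemRepeat) -> int:
    """Integer copy-number difference of a mapped read-TR vs its reference.

    delta = round((read array length - reference array length) / pattern
    length), rounded half away from zero.  Array length is orientation
    invariant, so no orientation normalization is needed here.
    """
    return _round_half_away((read_tr.array_len - ref.array_len) / ref.pattern_len)


def allele_support(deltas: Iterable[int], min_support: int = MIN_SUPPORT_DEFAULT
                   ) -> list[tuple[int, int]]:
    """Group read deltas into alleles; keep those with >= min_support reads."""
    counts: dict[int, int] = {}
    for d in deltas:
        counts[d] = counts.get(d, 0) + 1
    return sorted((d, n) for d, n in counts.items() if n >= min_support)


def categorize(supported: Sequence[tuple[int, int]], ref: TandemRepeat,
               ref_category: str = SINGLETON) -> GenotypeCall:
    """Build the genotype call for one locus from its supported alleles."""
    deltas = {d for d, _ in supported}
    if not supported:
        category = UNCALLED
    elif deltas == {0}:
        category = NOT_VNTR
    elif len(supported) == 1:
        category = INFERRED
    else:
        category = OBSERVED
    return GenotypeCall(
        ref_id=ref.id,
        ref_copies=_round_half_away(ref.copies),
        supported_alleles=list(supported),
        category=category,
        multi_allelic=len(supported) > 2,
        ref_category=ref_category,
    )


def call_locus(ref: TandemRepeat, read_trs: Sequence[TandemRepeat],
               min_support: int = MIN_SUPPORT_DEFAULT,
               ref_category: str = SINGLETON) -> GenotypeCall:
    """Genotype one locus from its mapped (deduplicated) read-TRs."""
    supported = allele_support(
        (read_copy_delta(rt, ref) for rt in read_trs), min_support
    )
    return categorize(supported, ref, ref_category)


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=vntrcall
##INFO=<ID=RU,Number=1,Type=String,Description="Repeat unit (consensus pattern)">
##INFO=<ID=RC,Number=1,Type=Integer,Description="Reference copy number (rounded)">
##INFO=<ID=CD,Number=.,Type=Integer,Description="Copy-number delta of each supported allele vs the reference">
##INFO=<ID=RS,Number=.,Type=Integer,Description="Read support of each supported allele">
##INFO=<ID=CAT,Number=1,Type=String,Description="Reference category (singleton or indistinguishable)">
##INFO=<ID=MULTI,Number=0,Type=Flag,Description="More than two supported alleles">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _alt_array(ref: TandemRepeat, delta: int) -> str:
    """Alternate array reconstructed by adding or removing whole
    consensus copies at the array's 3' end."""
    if delta > 0:
        return ref.array + ref.pattern * delta
    trim = -delta * ref.pattern_len
    return ref.array[: max(ref.pattern_len, ref.array_len - trim)]


def _genotype_alleles(call: GenotypeCall) -> list[int]:
    """Allele indices (0 = reference) forming the diploid genotype.

    One supported allele -> homozygous.  Two -> heterozygous.  More than
    two -> the two best-supported (ties resolved toward the smaller
    |delta|, then the smaller delta).
    """
    ordered = sorted(call.supported_alleles,
                     key=lambda a: (-a[1], abs(a[0]), a[0]))[:2]
    chosen = sorted(d for d, _ in ordered)
    alts = [d for d, _ in call.supported_alleles if d != 0]
    def index(d: int) -> int:
        return 0 if d == 0 else 1 + alts.index(d)
    idx = sorted(index(d) for d in chosen)
    if len(idx) == 1:
        idx = idx * 2
    return idx


def write_vcf(calls: Sequence[GenotypeCall], refset: ReferenceSet,
              sample_name: str, vntr_out: TextIO, all_out: TextIO) -> None:
    """Write the two-call-file contract: VNTRs only, and all genotyped loci.

    POS is the 1-based position of the anchor base immediately before
    the array; REF/ALT are anchor + array.  Loci with no supported
    allele are never emitted.
    """
    body_all: list[str] = []
    body_vntr: list[str] = []
    ordered = sorted(
        (c for c in calls if c.supported_alleles),
        key=lambda c: ((refset.by_id[c.ref_id].chrom or ""),
                       refset.by_id[c.ref_id].start or 0, c.ref_id),
    )
    for call in ordered:
        ref = refset.by_id[call.ref_id]
        if ref.left_flank:
            anchor = ref.left_flank[-1].upper()
            pos = ref.start  # 0-based anchor position -> 1-based = start
        else:
            anchor = "N"
            pos = max(ref.start, 1)
        alts = [d for d, _ in call.supported_alleles if d != 0]
        alt_field = ",".join(anchor + _alt_array(ref, d) for d in alts) or "."
        info = (
            f"RU={ref.pattern};RC={call.ref_copies};"
            f"CD={','.join(str(d) for d, _ in call.supported_alleles)};"
            f"RS={','.join(str(n) for _, n in call.supported_alleles)};"
            f"CAT={call.ref_category}"
        )
        if call.multi_allelic:
            info += ";MULTI"
        gt = "/".join(str(i) for i in _genotype_alleles(call))
        line = "\t".join([
            ref.chrom or ".", str(pos), call.ref_id, anchor + ref.array.upper(),
            alt_field, ".", "PASS", info, "GT", gt,
        ])
        body_all.append(line)
        if call.is_vntr:
            body_vntr.append(line)
    contigs = sorted({tr.chrom for tr in refset.repeats if tr.chrom})
    for out, body in ((vntr_out, body_vntr), (all_out, body_all)):
        out.write(_VCF_HEADER)
        for c in contigs:
            out.write(f"##contig=<ID={c}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  f"{sample_name}\n")
        for line in body:
            out.write(line + "\n")


def load_vcf_genotypes(path: str) -> dict[str, tuple[list[int], list[int]]]:
    """Read back an emitted VCF: ref_id -> (deltas, supports)."""
    out: dict[str, tuple[list[int], list[int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in fields[7].split(";")
            )
            deltas = [int(x) for x in info["CD"].split(",")]
            supports = [int(x) for x in info["RS"].split(",")]
            out[fields[2]] = (deltas, supports)
    return out


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

@dataclass
class MendelianReport:
    """Trio consistency over loci bi-allelic in all three samples."""

    n_common: int
    n_all_diff: int
    inconsistent: list[str]

    @property
    def n_inconsistent(self) -> int:
        return len(self.inconsistent)


def _biallelic(calls: dict[str, GenotypeCall]) -> dict[str, frozenset[int]]:
    return {
        rid: frozenset(c.deltas)
        for rid, c in calls.items()
        if len(c.supported_alleles) == 2
    }


def check_mendelian(child: dict[str, GenotypeCall], mother: dict[str, GenotypeCall],
                    father: dict[str, GenotypeCall]) -> MendelianReport:
    """Check Mendelian transmission at loci bi-allelic in the whole trio.

    A locus is consistent when the child's two alleles can be partitioned
    one from each parent.  Also counted is the subset of common loci at
    which all three genotypes differ (the strongest test against
    systematic allele mis-assignment).
    """
    c, m, f = _biallelic(child), _biallelic(mother), _biallelic(father)
    common = sorted(set(c) & set(m) & set(f))
    inconsistent = []
    n_all_diff = 0
    for rid in common:
        gc, gm, gf = c[rid], m[rid], f[rid]
        if gc != gm and gc != gf and gm != gf:
            n_all_diff += 1
        a, b = sorted(gc)
        ok = (a in gm and b in gf) or (a in gf and b in gm)
        if not ok:
            inconsistent.append(rid)
    return MendelianReport(n_common=len(common), n_all_diff=n_all_diff,
                           inconsistent=inconsistent)


# ---------------------------------------------------------------------------
# run summary
# ---------------------------------------------------------------------------

def summary_report(refset: ReferenceSet, n_read_trs: int,
                   mapped_per_ref: dict[str, int],
                   calls: Sequence[GenotypeCall]) -> dict[str, int]:
    """Per-run counts: references/read-TRs through each stage, mapped
    references by read depth, supported loci, and VNTRs by category with
    the singleton/indistinguishable split."""
    cats = refset.categories
    counts = {
        "refs_total": len(refset),
        "refs_singleton": sum(1 for r in refset.repeats
                              if cats.get(r.id, SINGLETON) == SINGLETON),
        "refs_indistinguishable": sum(1 for r in refset.repeats
                                      if cats.get(r.id) == "indistinguishable"),
        "read_trs_total": n_read_trs,
        "refs_mapped_ge1": sum(1 for n in mapped_per_ref.values() if n >= 1),
        "refs_mapped_ge2": sum(1 for n in mapped_per_ref.values() if n >= 2),
        "refs_with_support": sum(1 for c in calls if c.supported_alleles),
        "not_vntr": sum(1 for c in calls if c.category == NOT_VNTR),
        "inferred_vntr": sum(1 for c in calls if c.category == INFERRED),
        "observed_vntr": sum(1 for c in calls if c.category == OBSERVED),
        "observed_same_diff": sum(1 for c in calls if c.subtype() == "Same/Diff"),
        "observed_diff_diff": sum(1 for c in calls if c.subtype() == "Diff/Diff"),
        "multi_allelic": sum(1 for c in calls if c.multi_allelic),
        "vntr_total": sum(1 for c in calls if c.is_vntr),
        "vntr_singleton": sum(1 for c in calls
                              if c.is_vntr and c.ref_category == SINGLETON),
    }
    return counts
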