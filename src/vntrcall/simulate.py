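"""Validation data factory: synthetic genomes, planted VNTRs, diploid
read simulation with platform error models, and ground-truth read-TR
annotations for closed-loop testing.

The generator plants tandem arrays (random minisatellite patterns, a few
copies each) in random background sequence, introduces copy-number
variants of +/-1 or +/-2 pattern copies (homozygous or heterozygous),
draws reads uniformly from the two haplotypes, and optionally corrupts
them with a 454-style homopolymer indel model or an Illumina-style
position-dependent substitution model.  Because read origins are known,
ground-truth read-TR annotations (the role played by a tandem repeat
finder on real reads) are emitted for every read spanning a planted
array with enough flank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .profiles import TandemRepeat, revcomp
from .refset import ReferenceSet

_BASES = np.array(list("ACGT"))
_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}

VARIANT_DELTAS = (-2, -1, 1, 2)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

@dataclass
class LocusPlacement:
    """Where one planted locus sits on one haplotype."""

    chrom: str
    start: int
    end: int
    units: list[str]

    @property
    def array_len(self) -> int:
        return self.end - self.start


@dataclass
class Haplotype:
    name: str
    genome: dict[str, str]
    loci: dict[str, LocusPlacement]


@dataclass
class SimRead:
    """One simulated read with its origin record."""

    id: str
    haplotype: str
    chrom: str
    start: int  # 0-based on the source haplotype
    length: int  # error-free length on the haplotype
    strand: str  # "+" | "-"
    seq: str
    coord_map: Optional[list[int]] = None  # error-free read coord -> errored


@dataclass
class TruthRecord:
    ref_id: str
    delta_a: int
    delta_b: int
    zygosity: str  # "unmodified" | "homozygous" | "heterozygous"


@dataclass
class SimulatedDataset:
    haplotypes: list[Haplotype]
    truth: list[TruthRecord]
    reads: list[SimRead] = field(default_factory=list)
    seed: Optional[int] = None

    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.ref_id: t for t in self.truth}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_pattern(rng: np.random.Generator, length: int) -> str:
    while True:
        pat = _random_seq(rng, length)
        if len(set(pat)) >= 2:
            return pat


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = _OTHER[b][rng.integers(0, 3)]
    return "".join(out)


def plant_reference(genome_len: int = 1_000_000, n_loci: int = 300,
                    pattern_len_range: tuple[int, int] = (7, 60),
                    copy_range: tuple[int, int] = (2, 5),
                    seed: int = 0, mutation_rate: float = 0.0,
                    max_array_len: int = 120, min_separation: int = 100,
                    n_chroms: int = 1,
                    ) -> tuple[dict[str, str], ReferenceSet]:
    """Random genome with ``n_loci`` planted tandem arrays.

    Patterns are random minisatellites (>= 7 nt, >= 2 distinct bases);
    copies are drawn from ``copy_range`` resampled until the array fits
    ``max_array_len`` (arrays longer than read length minus two flanks
    cannot be genotyped by a spanning-read method, so the default keeps
    them well inside a 250 nt read).  Loci are separated by at least
    ``min_separation`` nt and placed deterministically under ``seed``.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = {f"chr{i + 1}": genome_len // n_chroms for i in range(n_chroms)}
    genome = {c: _random_seq(rng, ln) for c, ln in chrom_lengths.items()}
    repeats: list[TandemRepeat] = []
    if n_loci == 0:
        return genome, ReferenceSet(repeats=[], provenance={"planted": 0})
    per_chrom = [n_loci // n_chroms + (1 if i < n_loci % n_chroms else 0)
                 for i in range(n_chroms)]
    idx = 0
    for ci, (chrom, cn) in enumerate(zip(chrom_lengths, per_chrom)):
        clen = chrom_lengths[chrom]
        if cn == 0:
            continue
        region = clen // cn
        if region < max_array_len + 2 * min_separation:
            raise ValueError("infeasible packing: loci do not fit with the "
                             "required separation")
        seq = list(genome[chrom])
        for r in range(cn):
            idx += 1
            while True:
                plen = int(rng.integers(pattern_len_range[0], pattern_len_range[1] + 1))
                ncopies = int(rng.integers(copy_range[0], copy_range[1] + 1))
                if plen * ncopies <= max_array_len:
                    break
            pattern = _random_pattern(rng, plen)
            units = [_mutate(pattern, mutation_rate, rng) for _ in range(ncopies)]
            array = "".join(units)
            lo = r * region + min_separation
            hi = (r + 1) * region - min_separation - len(array)
            start = int(rng.integers(lo, hi + 1))
            seq[start : start + len(array)] = array
            repeats.append(TandemRepeat(
                id=f"ref{idx:05d}", pattern=pattern, array=array,
                copies=len(array) / plen, chrom=chrom, start=start,
                end=start + len(array), copy_units=units,
            ))
        genome[chrom] = "".join(seq)
    # flanks from the final genome
    for tr in repeats:
        g = genome[tr.chrom]
        tr.left_flank = g[max(0, tr.start - 100) : tr.start]
        tr.right_flank = g[tr.end : tr.end + 100]
    refset = ReferenceSet(repeats=repeats, provenance={"planted": len(repeats)})
    return genome, refset


# ---------------------------------------------------------------------------
# variant planting and haplotype construction
# ---------------------------------------------------------------------------

def _alt_units(units: Sequence[str], delta: int, rng: np.random.Generator) -> list[str]:
    """Duplicate or remove ``|delta|`` randomly chosen existing copies."""
    units = list(units)
    if delta > 0:
        for _ in range(delta):
            i = int(rng.integers(0, len(units)))
            units.insert(i, units[i])
    elif delta < 0:
        if len(units) + delta < 2:
            raise ValueError("removal would leave fewer than 2 copies")
        drop = sorted(rng.choice(len(units), size=-delta, replace=False),
                      reverse=True)
        for i in drop:
            del units[i]
    return units


def build_haplotype(name: str, genome: dict[str, str], refset: ReferenceSet,
                    alt_arrays: dict[str, list[str]]) -> Haplotype:
    """Splice per-locus (possibly alternate) arrays into the genome.

    ``alt_arrays`` maps ref_id -> copy-unit list; loci absent from it
    keep their reference units.  Coordinates on the new haplotype are
    recorded per locus.
    """
    loci: dict[str, LocusPlacement] = {}
    out_genome: dict[str, str] = {}
    by_chrom: dict[str, list[TandemRepeat]] = {}
    for tr in refset.repeats:
        by_chrom.setdefault(tr.chrom, []).append(tr)
    for chrom, seq in genome.items():
        trs = sorted(by_chrom.get(chrom, []), key=lambda t: t.start)
        pieces = []
        pos = 0
        offset = 0
        for tr in trs:
            units = alt_arrays.get(tr.id, tr.copy_units)
            if units is None:
                raise ValueError(f"no copy units known for {tr.id}")
            array = "".join(units)
            pieces.append(seq[pos : tr.start])
            new_start = tr.start + offset
            pieces.append(array)
            loci[tr.id] = LocusPlacement(chrom=chrom, start=new_start,
                                         end=new_start + len(array),
                                         units=list(units))
            offset += len(array) - (tr.end - tr.start)
            pos = tr.end
        pieces.append(seq[pos:])
        out_genome[chrom] = "".join(pieces)
    return Haplotype(name=name, genome=out_genome, loci=loci)


def plant_vntrs(refset: ReferenceSet, genome: dict[str, str],
                fraction: float = 0.005, zygosity: str = "homozygous",
                seed: int = 0, n_variants: Optional[int] = None,
                ) -> SimulatedDataset:
    """Create a diploid genome with copy-number variants at a subset of loci.

    ``ceil(fraction * n)`` loci (or ``n_variants`` when given) receive a
    delta drawn from {-2, -1, +1, +2}; removals that would leave fewer
    than two copies are redrawn.  Homozygous mode modifies both
    haplotypes; heterozygous mode modifies haplotype B only.
    """
    if zygosity not in ("homozygous", "heterozygous"):
        raise ValueError("zygosity must be homozygous or heterozygous")
    rng = np.random.default_rng(seed)
    n = len(refset.repeats)
    k = n_variants if n_variants is not None else math.ceil(fraction * n)
    ids = [tr.id for tr in refset.repeats]
    chosen = sorted(rng.choice(ids, size=k, replace=False)) if k else []
    alt: dict[str, list[str]] = {}
    truth: list[TruthRecord] = []
    deltas: dict[str, int] = {}
    for rid in chosen:
        tr = refset.by_id[rid]
        while True:
            delta = int(VARIANT_DELTAS[rng.integers(0, 4)])
            if len(tr.copy_units) + delta >= 2:
                break
        alt[rid] = _alt_units(tr.copy_units, delta, rng)
        deltas[rid] = delta
    for tr in refset.repeats:
        d = deltas.get(tr.id, 0)
        if d == 0:
            truth.append(TruthRecord(tr.id, 0, 0, "unmodified"))
        elif zygosity == "homozygous":
            truth.append(TruthRecord(tr.id, d, d, "homozygous"))
        else:
            truth.append(TruthRecord(tr.id, 0, d, "heterozygous"))
    hap_a = build_haplotype("hapA", genome, refset,
                            alt if zygosity == "homozygous" else {})
    hap_b = build_haplotype("hapB", genome, refset, alt)
    return SimulatedDataset(haplotypes=[hap_a, hap_b], truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class LengthModel:
    """Read-length model: fixed length, or truncated normal (454-like)."""

    kind: str  # "fixed" | "normal"
    length: int = 250
    mean: float = 261.0
    sd: float = 27.0
    min_length: int = 30

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.length, dtype=np.int64)
        if self.kind == "normal":
            draws = rng.normal(self.mean, self.sd, size=n)
            return np.maximum(np.rint(draws).astype(np.int64), self.min_length)
        raise ValueError(f"unknown length model {self.kind!r}")


def simulate_reads(haplotypes: Sequence[Haplotype], n_reads: int,
                   length_model: LengthModel, seed: int = 0) -> list[SimRead]:
    """Uniformly placed single-end reads from a uniformly chosen haplotype.

    Strand is uniform; minus-strand reads store the reverse complement
    of the genomic segment.  Lengths exceeding the chosen contig are
    truncated to it.
    """
    rng = np.random.default_rng(seed)
    lengths = length_model.sample(n_reads, rng)
    hap_idx = rng.integers(0, len(haplotypes), size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    chrom_lists = [sorted(h.genome) for h in haplotypes]
    reads: list[SimRead] = []
    for i in range(n_reads):
        hap = haplotypes[hap_idx[i]]
        chroms = chrom_lists[hap_idx[i]]
        weights = np.array([len(hap.genome[c]) for c in chroms], dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())] \
            if len(chroms) > 1 else chroms[0]
        clen = len(hap.genome[chrom])
        length = int(min(lengths[i], clen))
        start = int(rng.integers(0, clen - length + 1))
        seq = hap.genome[chrom][start : start + length]
        strand = "+" if strands[i] == 0 else "-"
        if strand == "-":
            seq = revcomp(seq)
        reads.append(SimRead(id=f"read{i:07d}", haplotype=hap.name, chrom=chrom,
                             start=start, length=length, strand=strand, seq=seq))
    return reads


# ---------------------------------------------------------------------------
# platform error models
# ---------------------------------------------------------------------------

def default_454_rates(run_length: int) -> tuple[float, float, float]:
    """(overcall, undercall, substitution) rates for a homopolymer run.

    Overcall/undercall grow linearly from 0.2%/0.1% at run length 2 to
    8%/5% at length >= 8; length-1 runs use half the length-2 indel
    rates and a 0.05% substitution rate.
    """
    if run_length <= 1:
        return 0.001, 0.0005, 0.0005
    x = (min(run_length, 8) - 2) / 6.0
    over = 0.002 + x * (0.08 - 0.002)
    under = 0.001 + x * (0.05 - 0.001)
    return over, under, 0.0


def apply_454_errors(seq: str, rng: np.random.Generator,
                     rates: Callable[[int], tuple[float, float, float]] = default_454_rates,
                     ) -> tuple[str, list[int]]:
    """Homopolymer-based 454 error model.

    Each maximal homopolymer run is independently lengthened or
    shortened by one base with run-length-dependent probability;
    length-1 runs may also be substituted.  Returns the mutated sequence
    and a boundary map M with M[p] = position in the new sequence of the
    boundary before original position p.
    """
    out: list[str] = []
    cmap = [0] * (len(seq) + 1)
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run_len = j - i
        over, under, sub = rates(run_len)
        u = rng.random()
        if u < over:
            emitted = seq[i] * (run_len + 1)
        elif u < over + under:
            emitted = seq[i] * (run_len - 1)
        elif run_len == 1 and u < over + under + sub:
            emitted = _OTHER[seq[i]][rng.integers(0, 3)] if seq[i] in _OTHER else seq[i]
        else:
            emitted = seq[i : j]
        base = cmap[i]
        for t in range(1, run_len + 1):
            cmap[i + t] = base + min(t, len(emitted))
        out.append(emitted)
        i = j
    return "".join(out), cmap


def default_illumina_sub_curve(pos: int, read_len: int) -> float:
    """Substitution rate ramping linearly from 0.1% to 1% across the read."""
    if read_len <= 1:
        return 0.001
    return 0.001 + (pos / (read_len - 1)) * (0.01 - 0.001)


def apply_illumina_errors(seq: str, rng: np.random.Generator,
                          sub_curve: Callable[[int, int], float] = default_illumina_sub_curve,
                          indel_rate: float = 0.0001,
                          ) -> tuple[str, list[int]]:
    """Position-dependent substitutions plus rare single-base indels.

    Substitution probability at position p is ``sub_curve(p, len)``
    (uniform choice among the three alternatives); insertions and
    deletions are single-base, position independent, each at
    ``indel_rate / 2``.  Returns (new sequence, boundary map) as in
    :func:`apply_454_errors`.
    """
    out: list[str] = []
    n = len(seq)
    cmap = [0] * (n + 1)
    for p, ch in enumerate(seq):
        cmap[p] = len(out)
        u = rng.random()
        if u < indel_rate / 2:  # deletion
            continue
        if u < indel_rate:  # insertion before this base
            out.append(_BASES[rng.integers(0, 4)])
        if rng.random() < sub_curve(p, n) and ch in _OTHER:
            out.append(_OTHER[ch][rng.integers(0, 3)])
        else:
            out.append(ch)
    cmap[n] = len(out)
    return "".join(out), cmap


def add_sequencing_errors(reads: Sequence[SimRead], platform: str,
                          seed: int = 0, **kwargs) -> list[SimRead]:
    """Apply a platform error model to every read (new read objects)."""
    rng = np.random.default_rng(seed)
    apply_fn = {"454": apply_454_errors, "illumina": apply_illumina_errors}[platform]
    out = []
    for r in reads:
        seq, cmap = apply_fn(r.seq, rng, **kwargs)
        out.append(SimRead(id=r.id, haplotype=r.haplotype, chrom=r.chrom,
                           start=r.start, length=r.length, strand=r.strand,
                           seq=seq, coord_map=cmap))
    return out


# ---------------------------------------------------------------------------
# ground-truth annotation
# ---------------------------------------------------------------------------

def annotate_ground_truth(reads: Sequence[SimRead], haplotypes: Sequence[Haplotype],
                          refset: ReferenceSet, min_flank: int = 20,
                          ) -> tuple[list[TandemRepeat], dict[tuple[str, int], str]]:
    """Emit read-TR records for reads spanning planted arrays.

    Plays the role of running a tandem repeat finder on the reads, using
    the known read origins instead.  A read annotates a locus when it
    covers the whole array with at least ``min_flank`` nt on both sides
    (evaluated after sequencing errors, via the read's coordinate map).
    Returns the annotations and the origin map read-TR id -> source
    reference id.
    """
    hap_by_name = {h.name: h for h in haplotypes}
    loci_by_chrom: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for h in haplotypes:
        for rid, pl in h.loci.items():
            loci_by_chrom.setdefault((h.name, pl.chrom), []).append(
                (pl.start, pl.end, rid))
    for key in loci_by_chrom:
        loci_by_chrom[key].sort()
    annotations: list[TandemRepeat] = []
    origins: dict[tuple[str, int], str] = {}
    for read in reads:
        loci = loci_by_chrom.get((read.haplotype, read.chrom), [])
        rstart, rend = read.start, read.start + read.length
        found = []
        for lstart, lend, rid in loci:
            if lstart - rstart < min_flank:
                continue
            if rend - lend < min_flank:
                if lstart >= rend:
                    break
                continue
            found.append((lstart, lend, rid))
        ordinal = 0
        spans = []
        for lstart, lend, rid in found:
            # local coordinates in the final (strand-oriented) read
            if read.strand == "+":
                ls, le = lstart - rstart, lend - rstart
            else:
                ls, le = read.length - (lend - rstart), read.length - (lstart - rstart)
            if read.coord_map is not None:
                ls, le = read.coord_map[ls], read.coord_map[le]
            spans.append((ls, le, rid))
        for ls, le, rid in sorted(spans):
            if ls < min_flank or len(read.seq) - le < min_flank or le <= ls:
                continue  # sequencing errors ate into the required flank
            ordinal += 1
            ref = refset.by_id[rid]
            pattern = ref.pattern if read.strand == "+" else revcomp(ref.pattern)
            array = read.seq[ls:le]
            annotations.append(TandemRepeat(
                id=f"{read.id}:{ordinal}",
                pattern=pattern, array=array,
                copies=len(array) / len(pattern),
                left_flank=read.seq[:ls], right_flank=read.seq[le:],
                source=(read.id, ordinal),
            ))
            origins[(read.id, ordinal)] = rid
    return annotations, origins


# ---------------------------------------------------------------------------
# spanning probability and trio construction
# ---------------------------------------------------------------------------

def expected_spanning(array_len: int, read_len: int, flank: int, genome_len: int,
                      n_reads: int, k: int = 1) -> float:
    """Probability that >= k of N uniformly placed fixed-length reads span
    a TR array of the given length with ``flank`` nt on both sides.

    Valid start positions v = max(0, L - A - 2f + 1); per-read spanning
    probability p = v / (G - L + 1); returns the Binomial(N, p) upper
    tail P(X >= k).
    """
    if read_len < 1 or genome_len < read_len:
        raise ValueError("need 1 <= read_len <= genome_len")
    v = max(0, read_len - array_len - 2 * flank + 1)
    p = v / (genome_len - read_len + 1)
    return float(binom.sf(k - 1, n_reads, p))


def make_trio(refset: ReferenceSet, genome: dict[str, str], seed: int = 0,
              fraction: float = 0.05, n_variants: Optional[int] = None,
              ) -> dict[str, SimulatedDataset]:
    """Simulate a mother/father/child trio with Mendelian transmission.

    A subset of loci receives one alternate allele (delta in
    {-2, -1, +1, +2}); each parent carries two independent draws from
    {reference, alternate}; the child inherits one uniformly chosen
    allele from each parent.  Alternate arrays are constructed once and
    shared, so transmitted alleles are identical by descent.
    """
    rng = np.random.default_rng(seed)
    n = len(refset.repeats)
    k = n_variants if n_variants is not None else math.ceil(fraction * n)
    ids = [tr.id for tr in refset.repeats]
    chosen = sorted(rng.choice(ids, size=k, replace=False)) if k else []
    alt_units: dict[str, list[str]] = {}
    alt_delta: dict[str, int] = {}
    for rid in chosen:
        tr = refset.by_id[rid]
        while True:
            d = int(VARIANT_DELTAS[rng.integers(0, 4)])
            if len(tr.copy_units) + d >= 2:
                break
        alt_units[rid] = _alt_units(tr.copy_units, d, rng)
        alt_delta[rid] = d
    genotypes: dict[str, dict[str, tuple[int, int]]] = {}
    for person in ("mother", "father"):
        genotypes[person] = {
            rid: (int(rng.integers(0, 2)), int(rng.integers(0, 2)))
            for rid in chosen
        }
    genotypes["child"] = {
        rid: (genotypes["mother"][rid][rng.integers(0, 2)],
              genotypes["father"][rid][rng.integers(0, 2)])
        for rid in chosen
    }
    out: dict[str, SimulatedDataset] = {}
    for person, gt in genotypes.items():
        alts = [{rid: alt_units[rid] for rid, g in gt.items() if g[h]}
                for h in (0, 1)]
        haps = [build_haplotype(f"{person}_hap{'AB'[h]}", genome, refset, alts[h])
                for h in (0, 1)]
        truth = []
        for tr in refset.repeats:
            g = gt.get(tr.id, (0, 0))
            d = alt_delta.get(tr.id, 0)
            da, db = d * g[0], d * g[1]
            if (da, db) == (0, 0):
                zyg = "unmodified"
            elif da == db:
                zyg = "homozygous"
            else:
                zyg = "heterozygous"
            truth.append(TruthRecord(tr.id, da, db, zyg))
        out[person] = SimulatedDataset(haplotypes=haps, truth=truth, seed=seed)
    return out
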