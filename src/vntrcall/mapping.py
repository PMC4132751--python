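"""Turn scored candidate pairs into final read-TR -> ref-TR mappings.

Selection follows a two-list best-score scheme: pairs are ranked once by
profile WS and once by flank error rate; a read-TR is mapped to a
reference only if that reference is its best in *both* lists.  Reads
touching too many references are discarded, and PCR duplicates mapped to
the same reference are collapsed to one representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

from .filters import lcs_length

ReadTRId = tuple[str, int]  # (read id, ordinal of the TR within the read)


@dataclass
class CandidatePair:
    """A read-TR/ref-TR pairing that passed all alignment filters.

    Scores are kept as exact rationals so ties compare exactly.
    """

    read_id: str
    ordinal: int
    ref_id: str
    ws: Fraction
    flank_rate: Fraction
    orientation: str = "forward"
    rotation: int = 0

    @property
    def read_tr_id(self) -> ReadTRId:
        return (self.read_id, self.ordinal)


@dataclass
class MappingSet:
    """Final assignments plus per-read-TR discard reasons."""

    assignments: dict[ReadTRId, str] = field(default_factory=dict)
    discarded: dict[ReadTRId, str] = field(default_factory=dict)

    def refs_per_read(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for (read_id, _), ref_id in self.assignments.items():
            out.setdefault(read_id, set()).add(ref_id)
        return out


def _best_pairs_one_list(pairs: Sequence[CandidatePair], better) -> set[tuple[ReadTRId, str]]:
    """One-list selection: (i) each read-TR keeps its best-scoring
    reference(s) including ties; (ii) each reference keeps, among
    read-TRs of the same read, only the best one (ties -> highest
    ordinal).  ``better(p, q)`` is a strict partial order on scores."""
    by_read_tr: dict[ReadTRId, list[CandidatePair]] = {}
    for p in pairs:
        by_read_tr.setdefault(p.read_tr_id, []).append(p)
    kept: list[CandidatePair] = []
    for plist in by_read_tr.values():
        best = None
        for p in plist:
            if best is None or better(p, best[0]):
                best = [p]
            elif not better(best[0], p):  # exact tie
                best.append(p)
        kept.extend(best)
    # stage (ii): per (reference, read) keep one read-TR
    by_ref_read: dict[tuple[str, str], CandidatePair] = {}
    for p in kept:
        key = (p.ref_id, p.read_id)
        q = by_ref_read.get(key)
        if q is None or better(p, q) or (not better(q, p) and p.ordinal > q.ordinal):
            by_ref_read[key] = p
    return {(p.read_tr_id, p.ref_id) for p in by_ref_read.values()}


def select_mappings(pairs: Sequence[CandidatePair]) -> MappingSet:
    """Two-list best-score selection merged by intersection.

    A read-TR maps to a reference only if that reference yields both its
    best profile score and its best flank score.  A read-TR left with
    two or more distinct best references is removed (reason "tie"); one
    whose two lists do not intersect is removed (reason "score-conflict").
    """
    profile_best = _best_pairs_one_list(pairs, lambda p, q: p.ws > q.ws)
    flank_best = _best_pairs_one_list(pairs, lambda p, q: p.flank_rate < q.flank_rate)
    merged = profile_best & flank_best
    by_read_tr: dict[ReadTRId, set[str]] = {}
    for read_tr_id, ref_id in merged:
        by_read_tr.setdefault(read_tr_id, set()).add(ref_id)
    result = MappingSet()
    for read_tr_id in sorted({p.read_tr_id for p in pairs}):
        refs = by_read_tr.get(read_tr_id, set())
        if len(refs) == 1:
            result.assignments[read_tr_id] = next(iter(refs))
        elif len(refs) > 1:
            result.discarded[read_tr_id] = "tie"
        else:
            result.discarded[read_tr_id] = "score-conflict"
    return result


def discard_conflicted_reads(mapping: MappingSet, read_lengths: dict[str, int],
                             refs_by_id: dict[str, object]) -> MappingSet:
    """Drop whole reads whose TRs map inconsistently.

    A read loses all assignments when its read-TRs map to three or more
    distinct references, or to exactly two references that are too far
    apart for the read length (different chromosomes, or a combined
    genomic span exceeding the read length).
    """
    per_read = mapping.refs_per_read()
    bad: dict[str, str] = {}
    for read_id, refs in per_read.items():
        if len(refs) >= 3:
            bad[read_id] = "multi-ref"
        elif len(refs) == 2:
            r1, r2 = (refs_by_id[r] for r in sorted(refs))
            if r1.chrom != r2.chrom:
                bad[read_id] = "span-conflict"
            else:
                span = max(r1.end, r2.end) - min(r1.start, r2.start)
                if span > read_lengths.get(read_id, 0):
                    bad[read_id] = "span-conflict"
    out = MappingSet(discarded=dict(mapping.discarded))
    for read_tr_id, ref_id in mapping.assignments.items():
        reason = bad.get(read_tr_id[0])
        if reason is None:
            out.assignments[read_tr_id] = ref_id
        else:
            out.discarded[read_tr_id] = reason
    return out


def is_pcr_duplicate(seq_a: str, seq_b: str) -> bool:
    """Two reads are duplicates if their lengths differ by at most two
    nucleotides and their LCS is no shorter than the shorter length
    minus 3."""
    la, lb = len(seq_a), len(seq_b)
    if abs(la - lb) > 2:
        return False
    return lcs_length(seq_a, seq_b) >= min(la, lb) - 3


def eliminate_pcr_duplicates(reads_per_ref: dict[str, list[tuple[str, str]]]
                             ) -> tuple[dict[str, list[tuple[str, str]]], dict[str, str]]:
    """Collapse PCR duplicates among the reads mapped to each reference.

    ``reads_per_ref`` maps ref_id -> list of (read_id, sequence).  The
    pairwise duplicate relation is closed transitively; each cluster
    keeps its longest read (ties -> lexicographically smallest id).
    Returns the deduplicated map and {dropped read_id: "pcr-duplicate"}.
    """
    dropped: dict[str, str] = {}
    out: dict[str, list[tuple[str, str]]] = {}
    for ref_id, reads in reads_per_ref.items():
        n = len(reads)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if abs(len(reads[i][1]) - len(reads[j][1])) <= 2 and \
                        is_pcr_duplicate(reads[i][1], reads[j][1]):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        clusters: dict[int, list[int]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(i)
        keep_ids = set()
        for members in clusters.values():
            rep = min(members, key=lambda i: (-len(reads[i][1]), reads[i][0]))
            keep_ids.add(rep)
            for i in members:
                if i != rep:
                    dropped[reads[i][0]] = "pcr-duplicate"
        out[ref_id] = [reads[i] for i in sorted(keep_ids)]
    return out, dropped
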