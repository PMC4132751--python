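"""Cheap candidate generation and pre-filtering.

Two stages run before the expensive confirmation alignments:

* a spaced-seed index over the reference consensus patterns (both
  orientations, cyclically extended so phase-shifted patterns share
  seeds) proposes candidate read-TR/ref-TR pairings;
* a longest-common-subsequence comparison of the consensus patterns,
  computed with the Allison-Dix bit-parallel algorithm, gates pairs
  before profile and flank alignment.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .profiles import TandemRepeat, revcomp

DEFAULT_SEED_SHAPE = "11011011"  # span 8, weight 6


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence of two strings.

    Bit-parallel (Allison-Dix) formulation: one machine word per row of
    the classic DP, using Python's arbitrary-precision integers as the
    bit vector so no word-boundary handling is needed.
    """
    m = len(a)
    if m == 0 or len(b) == 0:
        return 0
    masks: dict[str, int] = {}
    bit = 1
    for ch in a:
        masks[ch] = masks.get(ch, 0) | bit
        bit <<= 1
    full = (1 << m) - 1
    row = 0
    for ch in b:
        x = row | masks.get(ch, 0)
        row = x & ~(x - ((row << 1) | 1)) & full
    return row.bit_count()


def _spaced_kmers(seq: str, shape: str) -> Iterable[str]:
    """Spaced k-mers of ``seq`` (care positions of ``shape`` only)."""
    span = len(shape)
    care = [i for i, c in enumerate(shape) if c == "1"]
    for start in range(len(seq) - span + 1):
        yield "".join(seq[start + i] for i in care)


def _cyclic_extend(pattern: str, span: int) -> str:
    """Extend a pattern cyclically by span-1 characters (and up to at
    least one full span for patterns shorter than the seed)."""
    need = len(pattern) + span - 1
    reps = -(-need // len(pattern))
    return (pattern * reps)[:need]


@dataclass
class SeedIndex:
    """Spaced-seed index from extracted k-mer keys to reference TR ids."""

    shape: str
    table: dict[str, set[str]] = field(default_factory=dict)

    def lookup(self, key: str) -> set[str]:
        return self.table.get(key, set())


def build_seed_index(refs: Sequence[TandemRepeat], shape: str = DEFAULT_SEED_SHAPE) -> SeedIndex:
    """Index every spaced k-mer of every reference consensus pattern.

    Both the forward pattern and its reverse complement are indexed, each
    cyclically extended by (seed span - 1) characters so that all phase
    shifts of the pattern contribute the same key set.
    """
    if not refs:
        raise ValueError("reference set is empty")
    if not shape or shape[0] != "1" or shape[-1] != "1" or set(shape) - {"0", "1"}:
        raise ValueError("seed shape must be a 1/0 string starting and ending with 1")
    span = len(shape)
    table: dict[str, set[str]] = defaultdict(set)
    for ref in refs:
        pat = ref.pattern.upper()
        for seq in (pat, revcomp(pat)):
            for key in _spaced_kmers(_cyclic_extend(seq, span), shape):
                table[key].add(ref.id)
    return SeedIndex(shape=shape, table=dict(table))


def candidate_refs(read_tr: TandemRepeat, index: SeedIndex, min_shared: int = 1) -> set[str]:
    """Reference ids sharing >= ``min_shared`` spaced k-mers with the
    read-TR consensus (the index already covers both orientations)."""
    span = len(index.shape)
    hits: dict[str, int] = defaultdict(int)
    pat = read_tr.pattern.upper()
    for key in set(_spaced_kmers(_cyclic_extend(pat, span), index.shape)):
        for ref_id in index.lookup(key):
            hits[ref_id] += 1
    return {ref_id for ref_id, n in hits.items() if n >= min_shared}


def _rotational_lcs(a: str, b: str) -> int:
    """LCS of ``a`` against the best cyclic rotation of ``b``.

    Computed against ``b`` doubled, capped at the shorter original
    length (an LCS with b+b can never certify more than min(|a|,|b|)
    rotation-consistent matches).
    """
    raw = lcs_length(a, b + b)
    return min(raw, len(a), len(b))


def lcs_filter(pat_a: str, pat_b: str, min_lcs_frac: float = 0.85,
               max_len_diff_frac: float = 0.10) -> bool:
    """Consensus-pattern pre-filter before profile alignment.

    Pass iff the (rotation- and orientation-tolerant) LCS is at least
    ``min_lcs_frac`` of the shorter pattern AND the length difference is
    at most ``max_len_diff_frac`` of the shorter pattern.  Thresholds are
    compared in exact rational arithmetic.
    """
    if not pat_a or not pat_b:
        raise ValueError("patterns must be non-empty")
    a, b = pat_a.upper(), pat_b.upper()
    shorter = min(len(a), len(b))
    # length criterion (orientation-independent)
    if abs(len(a) - len(b)) * 100 > round(max_len_diff_frac * 100) * shorter:
        return False
    threshold_pct = round(min_lcs_frac * 100)
    for other in (b, revcomp(b)):
        if _rotational_lcs(a, other) * 100 >= threshold_pct * shorter:
            return True
    return False
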