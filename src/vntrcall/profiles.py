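"""Domain types for tandem repeats and normalized count profiles.

A tandem repeat (TR) array is summarized as a *normalized profile*: an
ordered list of count vectors, one per column of a multiple alignment of
the individual pattern copies.  Each column holds counts for A, C, G, T
and gap, rescaled so they always sum to 10 and snapped to the nearest of
the 1001 legal integer compositions of 10 into 5 parts.  Profiles are the
objects compared during read-to-reference confirmation alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib

# symbol order used everywhere: A, C, G, T, gap
SYMBOLS = "ACGT-"
A, C, G, T, GAP = range(5)

#: the constant all-gap column used when a profile column is aligned to a gap
GAP_COLUMN = (0, 0, 0, 0, 10)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(_COMP)[::-1]


@dataclass
class TandemRepeat:
    """One TR locus (reference) or one TR found in a read (read-TR).

    Coordinates are 0-based half-open internally; user-facing files use
    1-based inclusive coordinates.  ``source`` is ``(read_id, ordinal)``
    for read-TRs and ``None`` for reference loci.  Flanks are stored
    array-proximal: ``left_flank`` ends at the base immediately before
    the array, ``right_flank`` starts at the base immediately after.
    """

    id: str
    pattern: str
    array: str
    copies: float
    left_flank: str = ""
    right_flank: str = ""
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    source: Optional[tuple[str, int]] = None
    category: Optional[str] = None  # "singleton" | "indistinguishable"
    copy_units: Optional[list[str]] = None  # simulator-known copy decomposition

    @property
    def pattern_len(self) -> int:
        return len(self.pattern)

    @property
    def array_len(self) -> int:
        return len(self.array)

    def is_minisatellite(self) -> bool:
        return self.pattern_len >= 7

    def is_admissible(self, min_flank: int = 20) -> bool:
        """Record admissibility: minisatellite pattern, ~2+ copies, flanks."""
        return (
            self.is_minisatellite()
            and self.array_len >= 1.8 * self.pattern_len
            and len(self.left_flank) >= min_flank
            and len(self.right_flank) >= min_flank
        )


@dataclass
class Profile:
    """Ordered normalized count columns for one TR array.

    ``columns[i]`` is a 5-tuple ``(n_A, n_C, n_G, n_T, n_gap)`` summing
    to 10.  ``orientation`` records whether the profile was built from
    the forward or the reverse-complement copies.
    """

    columns: list[tuple[int, int, int, int, int]]
    orientation: str = "forward"

    def __len__(self) -> int:
        return len(self.columns)

    def gap_counts(self) -> list[int]:
        return [col[GAP] for col in self.columns]


def normalize_counts(raw: Sequence[float]) -> tuple[int, int, int, int, int]:
    """Snap a raw 5-part count vector to the closest composition of 10.

    The raw counts (A, C, G, T, gap) are first rescaled proportionally to
    sum 10, then mapped to the closest integer 5-vector summing to 10 by
    Euclidean distance.  Ties are broken by largest fractional remainder,
    then lowest symbol index (A < C < G < T < gap), which makes the result
    deterministic and equal to the largest-remainder apportionment.
    """
    if len(raw) != 5:
        raise ValueError("expected 5 counts (A, C, G, T, gap)")
    total = float(sum(raw))
    if total <= 0:
        raise ValueError("empty column: all counts are zero")
    scaled = [10.0 * x / total for x in raw]
    floors = [int(s) for s in scaled]
    remainders = [s - f for s, f in zip(scaled, floors)]
    short = 10 - sum(floors)
    # distribute the remaining units to the largest remainders; ties go to
    # the lowest symbol index.  This minimizes the Euclidean distance to
    # the scaled vector among all compositions of 10.
    order = sorted(range(5), key=lambda i: (-remainders[i], i))
    out = floors[:]
    for i in order[:short]:
        out[i] += 1
    return tuple(out)  # type: ignore[return-value]


def enumerate_normalized_vectors() -> list[tuple[int, int, int, int, int]]:
    """All integer 5-vectors with non-negative entries summing to 10.

    There are exactly C(14, 4) = 1001 of them.
    """
    vectors = []
    for a, c, g, t in itertools.product(range(11), repeat=4):
        rest = 10 - (a + c + g + t)
        if rest >= 0:
            vectors.append((a, c, g, t, rest))
    return vectors


def _align_copy_to_consensus(copy: str, consensus: str):
    """Global alignment of one pattern copy against the consensus.

    Returns ``(cols, inserts)`` where ``cols[j]`` is the copy character
    aligned to consensus position ``j`` ('-' for a gap) and ``inserts[g]``
    is the string inserted between consensus positions ``g-1`` and ``g``
    (keyed by gap slot ``g`` in ``0..len(consensus)``).
    """
    res = edlib.align(copy, consensus, task="path", mode="NW")
    cigar = res["cigar"]
    cols = ["-"] * len(consensus)
    inserts: dict[int, str] = {}
    qi = tj = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            for _ in range(n):
                cols[tj] = copy[qi]
                qi += 1
                tj += 1
        elif ch == "D":  # gap in the copy
            tj += n
        elif ch == "I":  # bases of the copy inserted relative to consensus
            inserts[tj] = inserts.get(tj, "") + copy[qi : qi + n]
            qi += n
        else:  # pragma: no cover - edlib emits only =XMID
            raise ValueError(f"unexpected cigar op {ch!r}")
    return cols, inserts


def build_profile(copies: Sequence[str], consensus: str,
                  orientation: str = "forward") -> Profile:
    """Build a normalized profile from pattern copies and their consensus.

    Each copy is star-aligned against the consensus by unit-cost global
    edit distance; per consensus column the A/C/G/T/gap counts are
    normalized with :func:`normalize_counts`.  N's are ignored.  Insertion
    columns (bases present in a copy but not the consensus) are retained
    only at gap slots where at least half of the copies carry a base.
    """
    if not copies:
        raise ValueError("at least one pattern copy is required")
    if not consensus:
        raise ValueError("consensus must be non-empty")
    n = len(copies)
    aligned_cols = []
    aligned_ins = []
    for cp in copies:
        cols, inserts = _align_copy_to_consensus(cp.upper(), consensus.upper())
        aligned_cols.append(cols)
        aligned_ins.append(inserts)

    def column_counts(chars: Iterable[str]):
        counts = [0, 0, 0, 0, 0]
        for ch in chars:
            idx = SYMBOLS.find(ch)
            if idx >= 0:
                counts[idx] += 1
            # N (or any non-ACGT-) is ignored
        if sum(counts) == 0:
            raise ValueError("column contains only N's")
        return normalize_counts(counts)

    out_columns = []
    k = len(consensus)
    for j in range(k + 1):
        # insertion columns at gap slot j (before consensus position j)
        depth = 0
        while True:
            present = sum(1 for ins in aligned_ins if len(ins.get(j, "")) > depth)
            if 2 * present < n:
                break
            chars = [
                ins.get(j, "")[depth] if len(ins.get(j, "")) > depth else "-"
                for ins in aligned_ins
            ]
            out_columns.append(column_counts(chars))
            depth += 1
        if j < k:
            out_columns.append(column_counts(cols[j] for cols in aligned_cols))
    return Profile(columns=out_columns, orientation=orientation)


def reverse_complement_profile(p: Profile) -> Profile:
    """Reverse column order; swap A<->T and C<->G counts; keep gaps."""
    rc_cols = [
        (col[T], col[G], col[C], col[A], col[GAP]) for col in reversed(p.columns)
    ]
    orientation = "reverse-complement" if p.orientation == "forward" else "forward"
    return Profile(columns=rc_cols, orientation=orientation)


def split_array_into_copies(array: str, pattern: str) -> list[str]:
    """Chop a tandem array into successive pattern copies.

    Greedy left-to-right segmentation: at each step the prefix of the
    remaining array whose edit distance to the consensus pattern is
    smallest is taken as the next copy (candidate lengths within +/-20%
    of the pattern length; ties prefer the length closest to the pattern
    length, then the shorter).  A trailing partial copy is kept.
    """
    plen = len(pattern)
    if plen == 0:
        raise ValueError("empty pattern")
    slack = max(1, plen // 5)
    copies = []
    pos = 0
    n = len(array)
    while n - pos > plen + slack:
        best = None
        for length in range(plen - slack, plen + slack + 1):
            if length <= 0 or pos + length > n:
                continue
            chunk = array[pos : pos + length]
            d = edlib.align(chunk, pattern, mode="NW")["editDistance"]
            key = (d, abs(length - plen), length)
            if best is None or key < best[0]:
                best = (key, length)
        copies.append(array[pos : pos + best[1]])
        pos += best[1]
    if pos < n:
        copies.append(array[pos:])
    return copies


def profile_for_tr(tr: TandemRepeat) -> Profile:
    """Normalized profile of one TR, from its array and consensus pattern."""
    copies = split_array_into_copies(tr.array.upper(), tr.pattern.upper())
    return build_profile(copies, tr.pattern.upper())
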