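"""Reference TR set curation.

Two operations from the reference-preparation stage are implemented:
redundancy elimination (overlapping annotations of one locus collapse to
a single repeat) and singleton/indistinguishable classification (a
reference confusable with another family member under profile plus
one-sided 50 nt flank comparison is flagged, since read mappings to it
are uncertain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment import (
    FLANK_ERR_MAX_DEFAULT,
    WS_MIN_DEFAULT,
    edit_distance,
    profile_align,
    ws_pass,
)
from .filters import build_seed_index, candidate_refs, lcs_filter, DEFAULT_SEED_SHAPE
from .profiles import Profile, TandemRepeat, profile_for_tr, revcomp

logger = logging.getLogger(__name__)

SINGLETON = "singleton"
INDISTINGUISHABLE = "indistinguishable"


@dataclass
class ReferenceSet:
    """Curated reference TRs plus per-filter provenance counts."""

    repeats: list[TandemRepeat]
    categories: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.by_id = {tr.id: tr for tr in self.repeats}

    def __len__(self) -> int:
        return len(self.repeats)

    def category(self, ref_id: str) -> str:
        return self.categories.get(ref_id, SINGLETON)


def _overlap(a: TandemRepeat, b: TandemRepeat) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _keep_of_pair(a: TandemRepeat, b: TandemRepeat) -> TandemRepeat:
    """Redundant pair resolution: longer array wins, then shorter
    period, then lower start coordinate."""
    ka = (-a.array_len, a.pattern_len, a.start, a.id)
    kb = (-b.array_len, b.pattern_len, b.start, b.id)
    return a if ka <= kb else b


def redundancy_eliminate(repeats: Sequence[TandemRepeat]) -> list[TandemRepeat]:
    """Collapse repeats overlapping by more than 50% of the shorter array.

    Applied iteratively in deterministic (chrom, start) order until no
    pair of retained repeats overlaps by more than half of either
    repeat's array length.
    """
    kept = sorted(repeats, key=lambda t: (t.chrom or "", t.start or 0, t.id))
    changed = True
    while changed:
        changed = False
        out: list[TandemRepeat] = []
        for tr in kept:
            drop_new = False
            for i, other in enumerate(out):
                ov = _overlap(tr, other)
                if ov == 0:
                    continue
                shorter = min(tr.array_len, other.array_len)
                if 2 * ov > shorter:  # strict > 50%
                    winner = _keep_of_pair(tr, other)
                    if winner is other:
                        drop_new = True
                    else:
                        out[i] = None  # type: ignore[call-overload]
                    changed = True
            out = [t for t in out if t is not None]
            if not drop_new:
                out.append(tr)
        kept = out
    return kept


def classify_indistinguishable(refset: ReferenceSet, flank_len: int = 50,
                               ws_min: float = WS_MIN_DEFAULT,
                               flank_err_max: float = FLANK_ERR_MAX_DEFAULT,
                               seed_shape: str = DEFAULT_SEED_SHAPE,
                               profiles: Optional[dict[str, Profile]] = None
                               ) -> dict[str, str]:
    """Self-map the reference set to flag confusable repeats.

    Every reference is compared against every other reference surviving
    the seed filter, with the usual consensus-LCS and profile-WS gates,
    but a modified flank test: it passes if *either* the left or the
    right flank, at exactly ``flank_len`` nt, aligns within
    ``flank_err_max`` errors (<= 5 errors for 50 nt).  Any non-self pass
    marks the query indistinguishable; all others are singletons.
    """
    max_err = int(flank_err_max * flank_len)
    index = build_seed_index(refset.repeats, seed_shape)
    if profiles is None:
        profiles = {tr.id: profile_for_tr(tr) for tr in refset.repeats}
    categories: dict[str, str] = {}
    for tr in refset.repeats:
        flagged = False
        left = tr.left_flank[-flank_len:].upper()
        right = tr.right_flank[:flank_len].upper()
        for other_id in sorted(candidate_refs(tr, index)):
            if other_id == tr.id:
                continue
            other = refset.by_id[other_id]
            if not lcs_filter(tr.pattern, other.pattern):
                continue
            res = profile_align(profiles[tr.id], profiles[other_id])
            if not ws_pass(res, ws_min):
                continue
            o_left = other.left_flank[-flank_len:].upper()
            o_right = other.right_flank[:flank_len].upper()
            if res.orientation == "forward":
                sides = ((left, o_left), (right, o_right))
            else:
                sides = ((revcomp(right), o_left), (revcomp(left), o_right))
            if any(edit_distance(a, b) <= max_err for a, b in sides if a and b):
                flagged = True
                break
        categories[tr.id] = INDISTINGUISHABLE if flagged else SINGLETON
    refset.categories.update(categories)
    for tr in refset.repeats:
        tr.category = categories[tr.id]
    return categories
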