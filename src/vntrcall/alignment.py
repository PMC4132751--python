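"""Confirmation alignments for candidate read-TR/ref-TR pairs.

Two independent alignments confirm a candidate pairing:

* *profile alignment* of the two TR arrays' normalized profiles, scored
  by gap-weighted scaled Euclidean distance between columns.  The
  weighted distance WD is converted to a pseudo-similarity

      WS = 100 - WD / (255 * sum(Weight_i)) * 100

  in [0, 100], where 255 is the worst possible scaled column distance
  and Weight_i = min(10, 20 - gaps(V) - gaps(W)) down-weights columns
  dominated by gaps.  A pairing must reach WS >= 88.

* *flank alignment* of the sequences adjacent to the arrays, by
  unit-cost edit distance, with at most 10% errors relative to the
  combined read flank lengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .profiles import GAP_COLUMN, Profile, reverse_complement_profile

logger = logging.getLogger(__name__)

WS_MIN_DEFAULT = 88.0
FLANK_ERR_MAX_DEFAULT = 0.10
BAND_DEFAULT = 5

_MAX_COLUMN_DISTANCE = 255
_SCALE = _MAX_COLUMN_DISTANCE / math.sqrt(200.0)  # sqrt(200) = worst distance


def edit_distance(a: str, b: str, mode: str = "global") -> int:
    """Unit-cost edit distance, bit-parallel (Myers 1999).

    ``mode="global"`` gives the Levenshtein distance between ``a`` and
    ``b``.  ``mode="infix"`` gives the minimum distance between ``a``
    and any substring of ``b`` (approximate substring search; the first
    DP row is all zeros).  Python's big integers serve as the bit
    vector, so patterns longer than a machine word need no blocking.
    """
    m = len(a)
    if m == 0:
        return len(b) if mode == "global" else 0
    peq: dict[str, int] = {}
    bit = 1
    for ch in a:
        peq[ch] = peq.get(ch, 0) | bit
        bit <<= 1
    full = (1 << m) - 1
    high = 1 << (m - 1)
    carry = 1 if mode == "global" else 0
    pv, mv, score = full, 0, m
    best = score
    for ch in b:
        eq = peq.get(ch, 0)
        xv = eq | mv
        xh = (((eq & pv) + pv) ^ pv) | eq
        ph = mv | ~(xh | pv)
        mh = pv & xh
        if ph & high:
            score += 1
        elif mh & high:
            score -= 1
        ph = ((ph << 1) | carry) & full
        mh = (mh << 1) & full
        pv = (mh | ~(xv | ph)) & full
        mv = ph & xv
        if score < best:
            best = score
    return best if mode == "infix" else score


def column_distance(v: Sequence[int], w: Sequence[int]) -> int:
    """Euclidean distance between two normalized columns, scaled to [0, 255].

    The worst case (two disjoint pure columns, distance sqrt(200)) maps
    to 255; values are rounded half-up to the nearest integer.
    """
    d = math.sqrt(sum((x - y) ** 2 for x, y in zip(v, w)))
    return int(math.floor(d * _SCALE + 0.5))


def position_weight(v: Sequence[int], w: Sequence[int]) -> int:
    """Gap-based weight of an aligned column pair: min(10, 20 - gaps(V) - gaps(W)),
    floored at 0."""
    return max(0, min(10, 20 - (v[4] + w[4])))


@dataclass
class ProfileAlignmentResult:
    """Outcome of a profile alignment.

    ``wd`` and ``weight_sum`` are exact integers; ``ws`` is derived.
    """

    wd: int
    weight_sum: int
    rotation: int
    orientation: str

    @property
    def ws(self) -> float:
        if self.weight_sum == 0:
            return 100.0
        return 100.0 - (self.wd / (255.0 * self.weight_sum)) * 100.0

    def ws_exact(self) -> Fraction:
        """WS as an exact rational, for tie comparisons."""
        if self.weight_sum == 0:
            return Fraction(100)
        return 100 - Fraction(self.wd * 100, 255 * self.weight_sum)


@dataclass
class FlankAlignmentResult:
    """Flank edit distances and the combined error rate."""

    left_errors: int
    right_errors: int
    combined_read_flank_len: int

    @property
    def total_errors(self) -> int:
        return self.left_errors + self.right_errors

    @property
    def error_rate(self) -> float:
        if self.combined_read_flank_len == 0:
            return 0.0 if self.total_errors == 0 else math.inf
        return self.total_errors / self.combined_read_flank_len

    def rate_exact(self) -> Fraction:
        if self.combined_read_flank_len == 0:
            return Fraction(0) if self.total_errors == 0 else Fraction(10**9)
        return Fraction(self.total_errors, self.combined_read_flank_len)

    def passes(self, max_rate: float = FLANK_ERR_MAX_DEFAULT) -> bool:
        return self.rate_exact() <= Fraction(str(max_rate))


def ws_pass(result: ProfileAlignmentResult, ws_min: float = WS_MIN_DEFAULT) -> bool:
    """WS threshold check (inclusive)."""
    return result.ws_exact() >= Fraction(str(ws_min))


# ---------------------------------------------------------------------------
# profile alignment DP kernel
# ---------------------------------------------------------------------------

_INF = np.int64(1) << np.int64(60)


def _rotation_dp_py(cost, wt, gc_a, gw_a, gc_b, gw_b, h, rotations):
    """Banded global DP over column profiles, best over cyclic rotations.

    Minimizes WD = sum(distance * weight); among equal-cost paths the one
    with the larger accumulated weight is kept (ties then prefer the
    diagonal, then the vertical move).  Returns (wd, weight_sum, rotation)
    of the rotation minimizing WD / weight_sum (i.e. maximizing WS).
    """
    k1, k2 = cost.shape
    INF = int(_INF)
    best_wd, best_wsum, best_rot = INF, 1, -1
    n_rot = k1 if rotations else 1
    F = [0] * (k2 + 1)
    W = [0] * (k2 + 1)
    Fp = [0] * (k2 + 1)
    Wp = [0] * (k2 + 1)
    for rot in range(n_rot):
        for j in range(k2 + 1):
            if j == 0:
                Fp[0], Wp[0] = 0, 0
            elif j <= h:
                Fp[j] = Fp[j - 1] + gc_b[j - 1]
                Wp[j] = Wp[j - 1] + gw_b[j - 1]
            else:
                Fp[j], Wp[j] = INF, 0
        for i in range(1, k1 + 1):
            src = (rot + i - 1) % k1
            jlo = i - h if i - h > 0 else 0
            jhi = i + h if i + h < k2 else k2
            for j in range(k2 + 1):
                F[j], W[j] = INF, 0
            for j in range(jlo, jhi + 1):
                bf, bw = INF, 0
                if j > 0 and Fp[j - 1] < INF:
                    bf = Fp[j - 1] + cost[src][j - 1]
                    bw = Wp[j - 1] + wt[src][j - 1]
                if Fp[j] < INF:
                    f = Fp[j] + gc_a[src]
                    w = Wp[j] + gw_a[src]
                    if f < bf or (f == bf and w > bw):
                        bf, bw = f, w
                if j > 0 and F[j - 1] < INF:
                    f = F[j - 1] + gc_b[j - 1]
                    w = W[j - 1] + gw_b[j - 1]
                    if f < bf or (f == bf and w > bw):
                        bf, bw = f, w
                F[j], W[j] = bf, bw
            F, Fp = Fp, F
            W, Wp = Wp, W
        wd, wsum = Fp[k2], Wp[k2]
        if wd >= INF:
            continue
        if best_rot < 0 or wd * best_wsum < best_wd * wsum:
            best_wd, best_wsum, best_rot = wd, max(wsum, 0), rot
            if best_wsum == 0:
                best_wsum = 1 if wd else 0
    return best_wd, best_wsum, best_rot


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit as _njit

    @_njit(cache=False)
    def _rotation_dp_nb(cost, wt, gc_a, gw_a, gc_b, gw_b, h, rotations):
        k1, k2 = cost.shape
        INF = np.int64(1) << np.int64(60)
        best_wd = INF
        best_wsum = np.int64(1)
        best_rot = -1
        n_rot = k1 if rotations else 1
        F = np.empty(k2 + 1, np.int64)
        W = np.empty(k2 + 1, np.int64)
        Fp = np.empty(k2 + 1, np.int64)
        Wp = np.empty(k2 + 1, np.int64)
        for rot in range(n_rot):
            Fp[0] = 0
            Wp[0] = 0
            for j in range(1, k2 + 1):
                if j <= h:
                    Fp[j] = Fp[j - 1] + gc_b[j - 1]
                    Wp[j] = Wp[j - 1] + gw_b[j - 1]
                else:
                    Fp[j] = INF
                    Wp[j] = 0
            for i in range(1, k1 + 1):
                src = (rot + i - 1) % k1
                jlo = i - h if i - h > 0 else 0
                jhi = i + h if i + h < k2 else k2
                for j in range(k2 + 1):
                    F[j] = INF
                    W[j] = 0
                for j in range(jlo, jhi + 1):
                    bf = INF
                    bw = np.int64(0)
                    if j > 0 and Fp[j - 1] < INF:
                        bf = Fp[j - 1] + cost[src, j - 1]
                        bw = Wp[j - 1] + wt[src, j - 1]
                    if Fp[j] < INF:
                        f = Fp[j] + gc_a[src]
                        w = Wp[j] + gw_a[src]
                        if f < bf or (f == bf and w > bw):
                            bf = f
                            bw = w
                    if j > 0 and F[j - 1] < INF:
                        f = F[j - 1] + gc_b[j - 1]
                        w = W[j - 1] + gw_b[j - 1]
                        if f < bf or (f == bf and w > bw):
                            bf = f
                            bw = w
                    F[j] = bf
                    W[j] = bw
                for j in range(k2 + 1):
                    Fp[j] = F[j]
                    Wp[j] = W[j]
            wd = Fp[k2]
            wsum = Wp[k2]
            if wd >= INF:
                continue
            if best_rot < 0 or wd * best_wsum < best_wd * wsum:
                best_wd = wd
                best_wsum = wsum if wsum > 0 else (np.int64(1) if wd else np.int64(0))
                best_rot = rot
        return best_wd, best_wsum, best_rot

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _rotation_dp_nb = None
    _HAVE_NUMBA = False


def _profile_arrays(p: Profile):
    cols = np.asarray(p.columns, dtype=np.int64)
    gaps = cols[:, 4]
    return cols, gaps


def _pair_matrices(pa: np.ndarray, pb: np.ndarray):
    """Cost and weight matrices for all column pairs of two profiles."""
    diff = pa[:, None, :] - pb[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    dist = np.floor(dist * _SCALE + 0.5).astype(np.int64)
    wt = 20 - (pa[:, 4][:, None] + pb[:, 4][None, :])
    wt = np.clip(wt, 0, 10).astype(np.int64)
    return dist * wt, wt


def _gap_vectors(cols: np.ndarray):
    """Per-column cost and weight against the all-gap column."""
    gap = np.asarray(GAP_COLUMN, dtype=np.int64)
    diff = cols - gap[None, :]
    dist = np.floor(np.sqrt((diff * diff).sum(axis=1)) * _SCALE + 0.5).astype(np.int64)
    wt = np.clip(20 - (cols[:, 4] + 10), 0, 10).astype(np.int64)
    return dist * wt, wt


def _run_dp(cost, wt, gc_a, gw_a, gc_b, gw_b, h, rotations):
    if _HAVE_NUMBA:
        return _rotation_dp_nb(cost, wt, gc_a, gw_a, gc_b, gw_b, h, rotations)
    return _rotation_dp_py(
        cost.tolist(), wt.tolist(), gc_a.tolist(), gw_a.tolist(),
        gc_b.tolist(), gw_b.tolist(), h, rotations,
    )


def profile_align(p_read: Profile, p_ref: Profile, band: Optional[int] = BAND_DEFAULT,
                  rotations: bool = True, try_reverse: bool = True) -> ProfileAlignmentResult:
    """Align two profiles, minimizing gap-weighted scaled Euclidean distance.

    The DP is global over the two column sequences; a column aligned to a
    gap is paired with the constant all-gap column (0,0,0,0,10), whose
    gap count feeds the position weight and so down-weights indels.  The
    DP is restricted to a diagonal band of half-width |k1-k2| + ``band``
    (``band=None`` disables banding).  All cyclic rotations of the read
    profile and, optionally, its reverse complement are tried; the
    rotation/orientation maximizing WS is returned.
    """
    if len(p_read) == 0 or len(p_ref) == 0:
        raise ValueError("profiles must be non-empty")
    k1, k2 = len(p_read), len(p_ref)
    if band is None:
        h = max(k1, k2)
    else:
        h = abs(k1 - k2) + max(1, int(band))
    pb, _ = _profile_arrays(p_ref)
    gc_b, gw_b = _gap_vectors(pb)
    candidates = [("forward", p_read)]
    if try_reverse:
        candidates.append(("reverse-complement", reverse_complement_profile(p_read)))
    best: Optional[ProfileAlignmentResult] = None
    for orientation, prof in candidates:
        pa, _ = _profile_arrays(prof)
        cost, wt = _pair_matrices(pa, pb)
        gc_a, gw_a = _gap_vectors(pa)
        wd, wsum, rot = _run_dp(cost, wt, gc_a, gw_a, gc_b, gw_b, h, rotations)
        if rot < 0:  # band failed to connect the corners; widen and retry
            logger.warning("alignment band too narrow (h=%d); widening", h)
            wd, wsum, rot = _run_dp(cost, wt, gc_a, gw_a, gc_b, gw_b,
                                    max(k1, k2), rotations)
        res = ProfileAlignmentResult(wd=int(wd), weight_sum=int(wsum),
                                     rotation=int(rot), orientation=orientation)
        if best is None or res.ws_exact() > best.ws_exact():
            best = res
    return best


def flank_align(read_left: str, read_right: str, ref_left: str, ref_right: str,
                flank_cap: Optional[int] = 50) -> FlankAlignmentResult:
    """Compare read flanks against reference flanks by edit distance.

    Flanks are truncated to their array-proximal ``flank_cap`` bases.
    On each side the shorter of the two sequences is located within the
    longer by approximate substring matching (infix edit distance), so a
    read flank extending past the available reference flank (or vice
    versa, at contig edges) is not penalized for the overhang.  The
    error rate is (left + right errors) / combined read flank length.
    """
    if flank_cap is not None:
        read_left = read_left[-flank_cap:] if flank_cap else read_left
        read_right = read_right[:flank_cap] if flank_cap else read_right
        ref_left = ref_left[-flank_cap:]
        ref_right = ref_right[:flank_cap]

    def side_errors(read_f: str, ref_f: str) -> int:
        if len(read_f) <= len(ref_f):
            return edit_distance(read_f, ref_f, mode="infix")
        return edit_distance(ref_f, read_f, mode="infix")

    return FlankAlignmentResult(
        left_errors=side_errors(read_left.upper(), ref_left.upper()),
        right_errors=side_errors(read_right.upper(), ref_right.upper()),
        combined_read_flank_len=len(read_left) + len(read_right),
    )
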