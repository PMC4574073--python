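"""Tandem repeat detection in nucleotide sequences.

Detects micro- and minisatellites (repeat units of 1--100 bp) whose
wraparound alignment against the cyclic consensus unit reaches a minimum
score under TRF-style weights (+2 match, -7 mismatch, -7 indel), with at
least 90 % unit identity and at most 10 % indels per adjacent-unit
junction.  The search is seeded: candidate periods are proposed from runs
of self-matches at distance ``p`` and verified by wraparound dynamic
programming; overlapping interpretations of the same locus are resolved
deterministically, highest score first.

Coordinates are 0-based, half-open, relative to the analysed region.
"""

from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._kernels import _consensus_numba, _enumerate_numba, align_stats

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_CODE = 4


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds and alignment weights for tandem repeat detection.

    Defaults follow Tandem Repeat Finder practice: with match weight +2 a
    perfect array needs >= 40 bp to reach the score threshold of 80.
    """

    min_score: int = 80
    max_unit_length: int = 100
    min_identity: float = 0.90
    max_indel_fraction: float = 0.10
    match_weight: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 7
    min_copy_number: float = 2.0
    max_n_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if not 1 <= self.max_unit_length <= 100:
            raise ValueError("max_unit_length must be in 1..100")
        for name in ("min_identity", "max_indel_fraction", "max_n_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.match_weight <= 0 or self.mismatch_penalty < 0 or self.indel_penalty < 0:
            raise ValueError("weights must be positive (penalties stored unsigned)")
        if self.min_copy_number < 1.0:
            raise ValueError("min_copy_number must be >= 1")

    @property
    def min_array_length(self) -> int:
        """Smallest array length that can reach min_score (score <= 2L)."""
        return -(-self.min_score // self.match_weight)


@dataclass(frozen=True)
class TandemRepeat:
    """One detected tandem repeat locus within a gene region."""

    start: int
    length: int
    unit: str
    period: int
    copy_number: float
    score: int
    identity: float
    indel_fraction: float
    gene_id: str = ""
    region_kind: str = ""

    @property
    def end(self) -> int:
        return self.start + self.length


def canonical_unit(unit: str) -> str:
    """Lexicographically minimal cyclic rotation of ``unit``.

    Idempotent; rotations of the same unit map to the same canonical form,
    which is what "repeats with the same repeat unit" compares.
    """
    if not unit:
        raise ValueError("empty unit")
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def is_mononucleotide(repeat: TandemRepeat) -> bool:
    """True iff the repeat's canonical unit is a single base."""
    return len(canonical_unit(repeat.unit)) == 1


def is_primitive_unit(unit: str) -> bool:
    """True when ``unit`` is not a whole-number power of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an A/C/G/T/N string to a uint8 code array (validates alphabet)."""
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(codes.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[codes == ord(base)] = code
    if (out == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(out == 255)[0][:5]})
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return out


def _junctions(length: int, period: int) -> int:
    return max(-(-length // period) - 1, 1)


def score_repeat_alignment(array: str, unit: str, params: DetectionParams | None = None):
    """Score a repeat array against cyclic concatenations of ``unit``.

    Global wraparound alignment with free start/end phase; the array must
    be fully consumed.  Returns ``(score, identity, indel_fraction)`` where
    identity is matches / aligned unit positions and indel_fraction is
    indels per adjacent-unit junction spanned by the array.
    """
    params = params or DetectionParams()
    if not unit:
        raise ValueError("empty unit")
    if len(unit) > params.max_unit_length:
        raise ValueError("unit longer than max_unit_length")
    a = encode_sequence(array)
    u = encode_sequence(unit)
    score, m, x, i = align_stats(a, u, params.match_weight,
                                 params.mismatch_penalty, params.indel_penalty)
    aligned = m + x
    identity = m / aligned if aligned else 0.0
    indel_fraction = i / _junctions(len(a), len(u)) if len(a) else 0.0
    return score, identity, indel_fraction


def _consensus_unit(array: np.ndarray, period: int) -> str | None:
    """Most frequent full-length unit among the array's aligned chunks.

    Ties broken lexicographically; chunks containing N are ignored.  Returns
    None when no N-free full chunk exists.
    """
    n_full = len(array) // period
    if n_full < 1:
        return None
    if period <= 26 and _consensus_numba is not None:
        best = int(_consensus_numba(array, period))
        if best < 0:
            return None
        out = []
        for _ in range(period):
            out.append("ACGT"[best % 5])
            best //= 5
        return "".join(reversed(out))
    buf = array[: n_full * period].reshape(n_full, period)
    clean = buf[~(buf == _N_CODE).any(axis=1)]
    if len(clean) == 0:
        return None
    counts: Counter[bytes] = Counter(row.tobytes() for row in clean)
    top = max(counts.values())
    chunk = min(k for k, v in counts.items() if v == top)
    return "".join("ACGT"[c] for c in chunk)


def _d_bound(length: int, period: int, params: DetectionParams) -> int:
    """Provable upper bound on self-mismatches at distance ``period``.

    For any array passing all thresholds with X mismatches and I indels in
    its optimal alignment, each mismatch breaks at most 2 of the distance-p
    self comparisons and each indel at most p + 2 (its phase shift spans p
    comparisons and an inserted base sits in two more), so
    d <= 2X + (p+2)I.  X and I are in turn bounded by the identity,
    indel-fraction and score thresholds.  Small slack is added; looseness
    costs verification work, never correctness.
    """
    w = params.match_weight
    pen = min(params.mismatch_penalty, params.indel_penalty)
    if pen == 0:
        return length
    budget = (w * length - params.min_score) // pen + 1
    if budget < 0:
        return -1
    # exact caps: identity >= mi forces X <= (1-mi)(M+X) <= (1-mi)L;
    # indel_fraction <= f forces I <= floor(f * junctions)
    x_max = int((1.0 - params.min_identity) * length + 1e-9)
    i_max = int(params.max_indel_fraction * _junctions(length, period) + 1e-9)
    # linear objective, indels have the larger coefficient (p+2 > 2)
    i_star = min(i_max, budget)
    x_star = max(min(x_max, budget - i_star), 0)
    return 2 * x_star + (period + 2) * i_star + 1


def _block_cost_prefix(mm: np.ndarray, period: int):
    """Per-block lower bounds on alignment events, for candidate pruning.

    The distance-p comparison axis is cut into blocks of size B separated by
    gaps of p + 1, so any single mismatch/indel (influence width <= p + 1)
    touches at most one block interior.  Block k with d_k self-mismatches
    then forces at least ceil(d_k / (p+2)) alignment events, and the bounds
    of disjoint blocks add up.  Returns (cost_prefix, block_size, stride).
    """
    B = 3 * (period + 2)
    stride = B + period + 1
    n_cmp = len(mm)
    n_blocks = n_cmp // stride
    if n_blocks == 0:
        return np.zeros(1, dtype=np.int64), B, stride
    d_k = (mm[: n_blocks * stride].reshape(n_blocks, stride)[:, :B]
           .sum(axis=1).astype(np.int64))
    cost = -(-d_k // (period + 2))
    return np.concatenate(([0], np.cumsum(cost))), B, stride


def _block_cost_sums(cost_prefix, B, stride, a: np.ndarray, e: np.ndarray):
    """Summed block costs for comparison intervals [a, e) (vectorised)."""
    k0 = -(-a // stride)
    k1 = (e - B) // stride
    n_blocks = len(cost_prefix) - 1
    k0c = np.clip(k0, 0, n_blocks)
    k1c = np.clip(k1 + 1, 0, n_blocks)
    out = cost_prefix[np.maximum(k1c, k0c)] - cost_prefix[k0c]
    return out


def _zero_runs(vec: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """[start, end) intervals of False-runs of ``vec`` at least min_len long."""
    ok = ~vec
    if not ok.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], ok, [False])).astype(np.int8)))
    return [(int(s), int(e)) for s, e in zip(idx[::2], idx[1::2])
            if e - s >= min_len]


def _majority_power_drop(keep, ca, cl, p, q, mm_p, mm_q):
    """Clear ``keep`` for candidates whose consensus is provably a power.

    If a stretch of >= m consecutive full p-chunks with 2m > n_chunks lies
    inside a region where both the distance-p and the distance-q (q | p)
    self-comparisons are clean, those chunks are identical q-powers and
    form a strict majority, so the consensus unit is non-primitive and
    verification would discard the candidate anyway.
    """
    combined = mm_p | mm_q[: len(mm_p)]
    for r0, r1 in _zero_runs(combined, 2 * p - q):
        nfull = cl // p
        k0 = np.maximum(-(-(r0 - ca) // p), 0)
        k1 = np.minimum((r1 + q - ca) // p, nfull)
        m = np.maximum(k1 - k0, 0)
        keep &= ~(2 * m > nfull)
    return keep


def _seed_windows(mm: np.ndarray, period: int, n: int,
                  seed_min: int = 5, join_gap: int = 40, margin: int = 50):
    """Intervals of the sequence worth searching for period-``p`` arrays.

    A window is anchored on runs of >= ``seed_min`` consecutive self-matches
    at distance ``period``; nearby runs are joined and a margin added so that
    mismatch-tolerant array boundaries stay inside the window.
    """
    ok = ~mm
    if not ok.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], ok, [False])).astype(np.int8)))
    starts, ends = idx[::2], idx[1::2]
    keep = (ends - starts) >= seed_min
    starts, ends = starts[keep], ends[keep]
    if len(starts) == 0:
        return []
    windows = []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s - cur_e <= join_gap:
            cur_e = int(e)
        else:
            windows.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    windows.append((cur_s, cur_e))
    pad = margin + period
    padded = [(max(0, s - pad), min(n, e + period + pad)) for s, e in windows]
    merged = [padded[0]]
    for lo, hi in padded[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _event_budget(length: int, period: int, params: DetectionParams) -> int:
    """Largest X + I compatible with the thresholds (padded, provable)."""
    w = params.match_weight
    pen = min(params.mismatch_penalty, params.indel_penalty)
    if pen == 0:
        return length
    budget = (w * length - params.min_score) // pen + 1
    if budget < 0:
        return -1
    x_max = int((1.0 - params.min_identity) * length + 1e-9)
    i_max = int(params.max_indel_fraction * _junctions(length, period) + 1e-9)
    return min(budget, x_max + i_max)


def _threshold_arrays(n: int, period: int, params: DetectionParams):
    """Vectors dmax[L], evmax[L] for L in 0..n (see _d_bound/_event_budget)."""
    L = np.arange(n + 1, dtype=np.int64)
    w = params.match_weight
    pen = min(params.mismatch_penalty, params.indel_penalty)
    junc = np.maximum(-(-L // period) - 1, 1)
    if pen == 0:
        return L.copy(), L.copy()
    budget = (w * L - params.min_score) // pen + 1
    x_max = ((1.0 - params.min_identity) * L + 1e-9).astype(np.int64)
    i_max = (params.max_indel_fraction * junc + 1e-9).astype(np.int64)
    i_star = np.minimum(i_max, budget)
    x_star = np.clip(np.minimum(x_max, budget - i_star), 0, None)
    dmax = 2 * x_star + (period + 2) * i_star + 1
    dmax[budget < 0] = -1
    evmax = np.minimum(budget, x_max + i_max)
    return dmax, evmax


def _enumerate_in_window(pref, n_pref, period, w_lo, w_hi, params,
                         blocks, thresholds):
    """Arrays (start, length, min_events) of all candidates in [w_lo, w_hi)
    passing the provable distance-p self-mismatch bounds and N-fraction cap."""
    cost_prefix, B, stride = blocks
    dmax_arr, evmax_arr = thresholds
    l_min = max(params.min_array_length,
                int(np.ceil(params.min_copy_number * period)))
    w_len = w_hi - w_lo
    if _enumerate_numba is not None:
        cap = max(4096, w_len * 8)
        while True:
            out_a = np.empty(cap, dtype=np.int64)
            out_len = np.empty(cap, dtype=np.int64)
            out_ev = np.empty(cap, dtype=np.int64)
            cnt = _enumerate_numba(pref, n_pref, cost_prefix, B, stride,
                                   period, w_lo, w_hi, l_min, dmax_arr,
                                   evmax_arr, params.max_n_fraction,
                                   out_a, out_len, out_ev)
            if cnt >= 0:
                break
            cap *= 4
        return out_a[:cnt], out_len[:cnt], out_ev[:cnt]
    chunks = []
    for length in range(l_min, w_len + 1):
        dmax = int(dmax_arr[length])
        if dmax < 0:
            continue
        max_events = int(evmax_arr[length])
        a = np.arange(w_lo, w_hi - length + 1)
        if len(a) == 0:
            continue
        span = length - period
        d = pref[a + span] - pref[a]
        blk = _block_cost_sums(cost_prefix, B, stride, a, a + span)
        min_events = np.maximum(-(-d // (period + 2)), blk)
        nfrac_ok = (n_pref[a + length] - n_pref[a]) <= params.max_n_fraction * length
        ok = (d <= dmax) & (min_events <= max_events) & nfrac_ok
        sel = np.flatnonzero(ok)
        if len(sel):
            chunks.append((a[sel], np.full(len(sel), length, dtype=np.int64),
                           min_events[sel]))
    if not chunks:
        z = np.empty(0, dtype=np.int64)
        return z, z, z
    return (np.concatenate([c[0] for c in chunks]),
            np.concatenate([c[1] for c in chunks]),
            np.concatenate([c[2] for c in chunks]))


def find_tandem_repeats(sequence: str, params: DetectionParams | None = None,
                        max_period: int | None = None,
                        gene_id: str = "", region_kind: str = "") -> list[TandemRepeat]:
    """Detect all tandem repeats in ``sequence`` passing the thresholds.

    Every maximal repeat array passing the score / identity / indel /
    unit-length criteria is reported exactly once after overlap resolution,
    sorted by start, with the unit in canonical cyclic form.
    """
    params = params or DetectionParams()
    if not sequence:
        return []
    codes = encode_sequence(sequence)
    n = len(codes)
    if max_period is None:
        max_period = params.max_unit_length
    max_period = min(max_period, params.max_unit_length,
                     int(n // params.min_copy_number))
    n_pref = np.concatenate(([0], np.cumsum((codes == _N_CODE).astype(np.int64))))
    pen = min(params.mismatch_penalty, params.indel_penalty)
    prefs: dict[int, np.ndarray] = {}
    mms: dict[int, np.ndarray] = {}
    chunks = []
    for p in range(1, max_period + 1):
        if n - p <= 0:
            continue
        mm = (codes[:-p] != codes[p:]) | (codes[:-p] == _N_CODE) | (codes[p:] == _N_CODE)
        windows = _seed_windows(mm, p, n)
        if not windows:
            continue
        pref = np.concatenate(([0], np.cumsum(mm.astype(np.int64))))
        prefs[p] = pref
        mms[p] = mm
        blocks = _block_cost_prefix(mm, p)
        thresholds = _threshold_arrays(n, p, params)
        parts_a, parts_l, parts_e = [], [], []
        for w_lo, w_hi in windows:
            wa, wl, we = _enumerate_in_window(pref, n_pref, p, w_lo, w_hi,
                                              params, blocks, thresholds)
            if len(wa):
                parts_a.append(wa)
                parts_l.append(wl)
                parts_e.append(we)
        if not parts_a:
            continue
        ca = np.concatenate(parts_a)
        cl = np.concatenate(parts_l)
        ce = np.concatenate(parts_e)
        # admissible score bound: the optimal alignment pays for >= ce events
        ub = params.match_weight * cl - pen * ce
        keep = ub >= params.min_score
        # consensus only sees full p-chunks; if that chunked span is exactly
        # periodic at a proper divisor q of p the consensus is a non-primitive
        # power, which verification would drop anyway
        for q in range(1, p):
            if p % q == 0 and q in prefs:
                pq = prefs[q]
                chunk_end = ca + p * (cl // p) - q
                keep &= (pq[chunk_end] - pq[ca]) != 0
                keep = _majority_power_drop(keep, ca, cl, p, q, mm, mms[q])
        if keep.any():
            sel = np.flatnonzero(keep)
            chunks.append((ca[sel], cl[sel],
                           np.full(len(sel), p, dtype=np.int64), ub[sel]))
    if not chunks:
        return []

    A = np.concatenate([c[0] for c in chunks])
    L = np.concatenate([c[1] for c in chunks])
    P = np.concatenate([c[2] for c in chunks])
    UB = np.concatenate([c[3] for c in chunks])
    # best-first total order: score bound, longer, leftmost, smaller period
    order = np.lexsort((P, A, -L, -UB))
    A = A[order].tolist()
    L = L[order].tolist()
    P = P[order].tolist()
    UB = UB[order].tolist()

    codes64 = codes.astype(np.int64)
    unit_codes_cache: dict[str, np.ndarray] = {}
    unit_memo: dict[tuple[int, int, int], str] = {}

    def unit_of(a: int, length: int, p: int) -> str:
        """Canonical consensus unit; "" when absent or non-primitive
        (primitivity is rotation-invariant, so it is tested pre-rotation)."""
        key = (a, length, p)
        u = unit_memo.get(key)
        if u is None:
            cu = _consensus_unit(codes[a:a + length], p)
            if cu is None or not is_primitive_unit(cu):
                u = ""
            else:
                u = canonical_unit(cu)
            unit_memo[key] = u
        return u

    accepted: list[tuple] = []  # (start, length, period, unit, score, id, if)

    def blocked(a: int, length: int, p: int) -> bool:
        # geometry first: >= 50 % overlap of the shorter conflicts whatever
        # the units are, so the (lazy) consensus is rarely needed
        for rec in accepted:
            ov = min(a + length, rec[0] + rec[1]) - max(a, rec[0])
            if ov <= 0:
                continue
            if ov >= 0.5 * min(length, rec[1]):
                return True
            if unit_of(a, length, p) == rec[3]:
                return True
        return False

    # lazy best-first selection: unverified candidates are consumed from the
    # sorted arrays, verified ones wait in a heap keyed by their true score;
    # the accepted set equals eager verification of every candidate
    heap: list[tuple] = []
    i = 0
    n_c = len(A)
    while i < n_c or heap:
        use_heap = bool(heap) and (
            i >= n_c or heap[0][0] < (-UB[i], -L[i], A[i], P[i]))
        if use_heap:
            _, rec = heapq.heappop(heap)
            if not blocked(rec[0], rec[1], rec[2]):
                accepted.append(rec)
            continue
        a, length, p = A[i], L[i], P[i]
        i += 1
        if blocked(a, length, p):
            continue
        u = unit_of(a, length, p)
        # "" covers both no-consensus and (redundant) non-primitive units
        if not u:
            continue
        uc = unit_codes_cache.get(u)
        if uc is None:
            uc = encode_sequence(u).astype(np.int64)
            unit_codes_cache[u] = uc
        score, m, x, ind = align_stats(codes64[a:a + length], uc,
                                       params.match_weight,
                                       params.mismatch_penalty,
                                       params.indel_penalty)
        aligned = m + x
        identity = m / aligned if aligned else 0.0
        indel_fraction = ind / _junctions(length, p)
        if (score >= params.min_score
                and identity >= params.min_identity
                and indel_fraction <= params.max_indel_fraction):
            heapq.heappush(heap, ((-score, -length, a, p),
                                  (a, length, p, u, score, identity,
                                   indel_fraction)))

    accepted.sort(key=lambda r: (r[0], r[2]))
    return [
        TandemRepeat(start=a, length=length, unit=u, period=p,
                     copy_number=length / p, score=score, identity=identity,
                     indel_fraction=indel_fraction,
                     gene_id=gene_id, region_kind=region_kind)
        for a, length, p, u, score, identity, indel_fraction in accepted
    ]
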