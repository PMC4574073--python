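"""Exhaustive reference search for tandem repeats (validation oracle).

Enumerates every (start, length, period) candidate in a sequence, scores
each surviving candidate with the wraparound alignment, applies the
detection thresholds, and resolves overlaps with its own eager greedy
pass.  Unlike the seeded detector it never restricts the search to
candidate windows, so it serves as the ground truth the detector is
validated against.  The pruning steps are *provable* necessary conditions
shared with the detector's contract, so the pruned enumeration equals the
unpruned one:

* ``score <= match_weight * length`` bounds the minimum array length;
* the optimal alignment's mismatch count X and indel count I obey
  ``d <= 2X + (p+2)I`` where d is the number of self-mismatches at
  distance p, and X, I are capped by the identity, indel-fraction and
  score thresholds (totals and per disjoint block);
* candidates whose consensus unit is provably a non-primitive power of a
  shorter unit are dropped, as verification would discard them.

Intended for sequences up to a few hundred bp; cost grows quadratically.
"""

from __future__ import annotations

import numpy as np

from ._kernels import align_stats
from .repeat_finder import (
    DetectionParams,
    TandemRepeat,
    _N_CODE,
    _block_cost_prefix,
    _block_cost_sums,
    _consensus_unit,
    _junctions,
    _majority_power_drop,
    _threshold_arrays,
    canonical_unit,
    encode_sequence,
    is_primitive_unit,
)


def _overlap_conflict(a, b) -> bool:
    # (start, length, unit, ...) tuples; same rule as the detector contract
    ov = min(a[0] + a[1], b[0] + b[1]) - max(a[0], b[0])
    if ov <= 0:
        return False
    if a[2] == b[2]:
        return True
    return ov >= 0.5 * min(a[1], b[1])


def brute_force_repeats(sequence: str, params: DetectionParams | None = None,
                        max_period: int = 10) -> list[TandemRepeat]:
    """Exhaustive-search equivalent of ``find_tandem_repeats``.

    Considers every (start, length, period <= max_period) triple, verifies
    each surviving candidate by full wraparound alignment against its
    consensus unit, and greedily keeps the best-scoring non-conflicting set.
    """
    params = params or DetectionParams()
    if not sequence:
        return []
    codes = encode_sequence(sequence)
    n = len(codes)
    n_pref = np.concatenate(([0], np.cumsum((codes == _N_CODE).astype(np.int64))))
    passing = []  # (start, length, unit, period, score, identity, indel_fraction)
    unit_cache: dict[str, np.ndarray] = {}
    max_period = min(max_period, params.max_unit_length,
                     int(n // params.min_copy_number))
    prefs: dict[int, np.ndarray] = {}
    mms: dict[int, np.ndarray] = {}
    for p in range(1, max_period + 1):
        if n - p <= 0:
            continue
        mm = (codes[:-p] != codes[p:]) | (codes[:-p] == _N_CODE) | (codes[p:] == _N_CODE)
        pref = np.concatenate(([0], np.cumsum(mm.astype(np.int64))))
        prefs[p] = pref
        mms[p] = mm
        divisors = [q for q in range(1, p) if p % q == 0 and q in prefs]
        cost_prefix, B, stride = _block_cost_prefix(mm, p)
        dmax_arr, evmax_arr = _threshold_arrays(n, p, params)
        l_min = max(params.min_array_length,
                    int(np.ceil(params.min_copy_number * p)))
        if l_min > n:
            continue
        lengths = np.arange(l_min, n + 1, dtype=np.int64)
        lengths = lengths[dmax_arr[lengths] >= 0]
        if len(lengths) == 0:
            continue
        L = lengths[:, None]
        a = np.arange(0, n - l_min + 1, dtype=np.int64)[None, :]
        valid = a <= n - L
        a_safe = np.where(valid, a, 0)
        end = np.where(valid, a_safe + L - p, 0)
        d = pref[end] - pref[a_safe]
        nfrac = n_pref[np.where(valid, a_safe + L, 0)] - n_pref[a_safe]
        blk = _block_cost_sums(cost_prefix, B, stride, a_safe, end)
        ok = (valid & (d <= dmax_arr[L]) & (blk <= evmax_arr[L])
              & (nfrac <= params.max_n_fraction * L))
        # provable non-primitive-consensus drops (shared contract)
        ca = np.broadcast_to(a_safe, ok.shape)
        cl = np.broadcast_to(L, ok.shape)
        for q in divisors:
            pq = prefs[q]
            chunk_end = np.where(valid, ca + p * (cl // p) - q, 0)
            ok &= (pq[chunk_end] - pq[ca]) != 0
            okf = ok.ravel()
            okf = _majority_power_drop(okf, ca.ravel(), cl.ravel(), p, q,
                                       mm, mms[q])
            ok = okf.reshape(ok.shape)
        for li, ai in zip(*np.nonzero(ok)):
            a0 = int(a_safe[0, ai])
            length = int(lengths[li])
            arr = codes[a0:a0 + length]
            unit = _consensus_unit(arr, p)
            if unit is None or not is_primitive_unit(unit):
                continue
            cu = canonical_unit(unit)
            u = unit_cache.get(cu)
            if u is None:
                u = encode_sequence(cu)
                unit_cache[cu] = u
            score, m, x, i = align_stats(arr, u, params.match_weight,
                                         params.mismatch_penalty,
                                         params.indel_penalty)
            aligned = m + x
            identity = m / aligned if aligned else 0.0
            indel_fraction = i / _junctions(length, p)
            if (score >= params.min_score
                    and identity >= params.min_identity
                    and indel_fraction <= params.max_indel_fraction):
                passing.append((a0, length, cu, p, score, identity,
                                indel_fraction))

    # eager greedy: best score, then longest, then leftmost, then smallest period
    passing.sort(key=lambda t: (-t[4], -t[1], t[0], t[3]))
    kept = []
    for cand in passing:
        if not any(_overlap_conflict(cand, k) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda t: (t[0], t[3]))
    return [
        TandemRepeat(start=a0, length=length, unit=cu, period=p,
                     copy_number=length / p, score=score,
                     identity=identity, indel_fraction=indel_fraction)
        for a0, length, cu, p, score, identity, indel_fraction in kept
    ]
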