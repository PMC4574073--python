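"""Inner alignment kernel for wraparound repeat scoring.

The dynamic programme packs (score, -indels, -mismatches) into one integer
so a single max gives the lexicographically best alignment: highest score,
then fewest indels, then fewest mismatches.  A numba-compiled kernel is
used when available; the pure-Python fallback is semantically identical.
"""

from __future__ import annotations

import numpy as np

_N_CODE = 4

# int64 packing: ((score + 2^20) << 30) + ((2^14 - indels) << 15) + (2^14 - mism)
_OFF = 1 << 20
_F = 1 << 14
_MASK = (1 << 15) - 1

_MAX_ARRAY = _F - 2  # fields must not under/overflow


def _align_python(arr, unit, w, pm, pi):
    L = len(arr)
    p = len(unit)
    d_match = w << 30
    d_mis = -((pm << 30) + 1)
    d_ind = -((pi << 30) + (1 << 15))
    base = (_OFF << 30) + (_F << 15) + _F
    row = [base] * p
    unit_l = [int(c) for c in unit]
    for a in arr:
        a = int(a)
        new = [v + d_ind for v in row]
        prev_j = p - 1
        for j in range(p):
            u = unit_l[prev_j]
            cand = row[prev_j] + (d_match if (a == u and a != _N_CODE) else d_mis)
            if cand > new[j]:
                new[j] = cand
            prev_j = j
        for _ in range(2):
            prev_j = p - 1
            changed = False
            for j in range(p):
                cand = new[prev_j] + d_ind
                if cand > new[j]:
                    new[j] = cand
                    changed = True
                prev_j = j
            if not changed:
                break
        row = new
    return max(row)


try:  # pragma: no cover - exercised when numba is installed
    from numba import njit

    @njit(cache=True)
    def _align_numba(arr, unit, w, pm, pi):  # pragma: no cover
        L = arr.shape[0]
        p = unit.shape[0]
        d_match = np.int64(w) << 30
        d_mis = -((np.int64(pm) << 30) + 1)
        d_ind = -((np.int64(pi) << 30) + (1 << 15))
        base = (np.int64(_OFF) << 30) + (np.int64(_F) << 15) + np.int64(_F)
        row = np.full(p, base, dtype=np.int64)
        new = np.empty(p, dtype=np.int64)
        for i in range(L):
            a = arr[i]
            for j in range(p):
                new[j] = row[j] + d_ind
            prev_j = p - 1
            for j in range(p):
                u = unit[prev_j]
                if a == u and a != 4:
                    cand = row[prev_j] + d_match
                else:
                    cand = row[prev_j] + d_mis
                if cand > new[j]:
                    new[j] = cand
                prev_j = j
            for _ in range(2):
                prev_j = p - 1
                changed = False
                for j in range(p):
                    cand = new[prev_j] + d_ind
                    if cand > new[j]:
                        new[j] = cand
                        changed = True
                    prev_j = j
                if not changed:
                    break
            for j in range(p):
                row[j] = new[j]
        best = row[0]
        for j in range(1, p):
            if row[j] > best:
                best = row[j]
        return best

    @njit(cache=True)
    def _consensus_numba(arr, period):  # pragma: no cover
        """Most frequent N-free chunk, base-5 packed; ties -> smallest
        packed value (= lexicographically smallest chunk).  -1 if none."""
        n_full = arr.shape[0] // period
        packed = np.empty(n_full, dtype=np.int64)
        m = 0
        for k in range(n_full):
            v = np.int64(0)
            ok = True
            for j in range(period):
                c = arr[k * period + j]
                if c == 4:
                    ok = False
                    break
                v = v * 5 + c
            if ok:
                packed[m] = v
                m += 1
        if m == 0:
            return np.int64(-1)
        sub = np.sort(packed[:m])
        best_val = sub[0]
        best_cnt = 1
        cur_val = sub[0]
        cur_cnt = 1
        for i in range(1, m):
            if sub[i] == cur_val:
                cur_cnt += 1
            else:
                cur_val = sub[i]
                cur_cnt = 1
            if cur_cnt > best_cnt:
                best_cnt = cur_cnt
                best_val = cur_val
        return best_val

    @njit(cache=True)
    def _enumerate_numba(pref, npref, costpref, B, stride, p, w_lo, w_hi,
                         l_min, dmax_arr, evmax_arr, max_nfrac,
                         out_a, out_len, out_ev):  # pragma: no cover
        """All (start, length) in [w_lo, w_hi) passing the provable
        self-mismatch, block-cost and N-fraction filters."""
        cnt = 0
        cap = out_a.shape[0]
        n_blocks = costpref.shape[0] - 1
        w_len = w_hi - w_lo
        for L in range(l_min, w_len + 1):
            dm = dmax_arr[L]
            if dm < 0:
                continue
            ev = evmax_arr[L]
            span = L - p
            for a in range(w_lo, w_hi - L + 1):
                d = pref[a + span] - pref[a]
                if d > dm:
                    continue
                if npref[a + L] - npref[a] > max_nfrac * L:
                    continue
                k0 = -((-a) // stride)
                k1 = (a + span - B) // stride
                k0c = min(max(k0, 0), n_blocks)
                k1c = min(max(k1 + 1, 0), n_blocks)
                blk = costpref[k1c] - costpref[k0c] if k1c > k0c else 0
                me = (d + p + 1) // (p + 2)
                if blk > me:
                    me = blk
                if me > ev:
                    continue
                if cnt >= cap:
                    return -1  # caller grows the buffers and retries
                out_a[cnt] = a
                out_len[cnt] = L
                out_ev[cnt] = me
                cnt += 1
        return cnt

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False
    _consensus_numba = None
    _enumerate_numba = None


def align_stats(arr: np.ndarray, unit: np.ndarray, w: int, pm: int, pi: int):
    """Optimal wraparound alignment of ``arr`` against cyclic ``unit``.

    Returns (score, matches, mismatches, indels); ties on score prefer
    fewer indels, then fewer mismatches.
    """
    L = len(arr)
    if L == 0:
        return 0, 0, 0, 0
    if L > _MAX_ARRAY:
        raise ValueError(f"array longer than {_MAX_ARRAY} bp not supported")
    if len(unit) == 1:
        # for a 1-bp unit mismatches dominate equal-cost insertions
        u = int(unit[0])
        m = int(np.count_nonzero(arr == u)) if u != _N_CODE else 0
        x = L - m
        return w * m - pm * x, m, x, 0
    if _HAVE_NUMBA:
        a64 = arr if arr.dtype == np.int64 else arr.astype(np.int64)
        u64 = unit if unit.dtype == np.int64 else unit.astype(np.int64)
        packed = int(_align_numba(a64, u64, w, pm, pi))
    else:
        packed = _align_python(arr, unit, w, pm, pi)
    mism = _F - (packed & _MASK)
    packed >>= 15
    ind = _F - (packed & _MASK)
    score = (packed >> 15) - _OFF
    matches = (score + pm * mism + pi * ind) // w
    return score, matches, mism, ind
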