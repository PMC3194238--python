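"""Hot search loops, JIT-compiled when numba is available.

Everything here operates on raw arrays (2-bit codes, sparse suffix
array rows, partition-table bounds) so the same source runs either
under numba or as plain Python when numba is missing. The end-of-text
sentinel is implicit: positions past the end of ``codes`` compare
smaller than any base.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def deco(func):
            return func

        return deco


@njit(cache=True)
def cmp_suffix(codes, pos, q):
    """Compare the suffix at ``pos`` against ``q`` over ``len(q)`` bases.

    Returns -1 / 0 / +1 for suffix < q, q-is-a-prefix-of-suffix,
    suffix > q. Running past the end of the text (the sentinel) makes
    the suffix compare smaller.
    """
    n = codes.shape[0]
    for j in range(q.shape[0]):
        if pos + j >= n:
            return -1
        c = codes[pos + j]
        if c < q[j]:
            return -1
        if c > q[j]:
            return 1
    return 0


@njit(cache=True)
def lcp_at(codes, pos, q):
    """Length of the longest common prefix of the suffix at ``pos`` and ``q``."""
    n = codes.shape[0]
    length = 0
    for j in range(q.shape[0]):
        if pos + j >= n or codes[pos + j] != q[j]:
            break
        length += 1
    return length


@njit(cache=True)
def range_search(codes, ssa, d, table, k_len, q, use_table):
    """Maximal half-open SSA row range whose suffixes start with ``q``.

    When ``use_table`` and ``len(q) >= k_len`` the search is narrowed to
    the partition-table interval of the first ``k_len`` bases first; the
    table stores, for absent K-mers, the insertion point among all rows,
    so both paths land on the same global range.
    """
    ns = ssa.shape[0]
    lo = 0
    hi = ns
    if use_table and q.shape[0] >= k_len:
        code = 0
        for j in range(k_len):
            code = code * 4 + q[j]
        lo = np.int64(table[code, 0])
        hi = np.int64(table[code, 1])
    a, b = lo, hi
    while a < b:
        mid = (a + b) // 2
        if cmp_suffix(codes, np.int64(ssa[mid]) * d, q) < 0:
            a = mid + 1
        else:
            b = mid
    sp = a
    b = hi
    while a < b:
        mid = (a + b) // 2
        if cmp_suffix(codes, np.int64(ssa[mid]) * d, q) <= 0:
            a = mid + 1
        else:
            b = mid
    return sp, a


@njit(cache=True)
def search_with_lmp(codes, ssa, d, table, k_len, q, use_table):
    """Range search plus the longest-matching-prefix length on a miss.

    Returns ``(sp, ep, L)``. On a hit ``L == len(q)``; on a miss ``L`` is
    the maximum matching-prefix length of ``q`` against the two rows
    adjacent to the binary-search insertion point, which by sortedness
    equals the maximum over all sampled suffixes.
    """
    sp, ep = range_search(codes, ssa, d, table, k_len, q, use_table)
    if sp < ep:
        return sp, ep, q.shape[0]
    best = 0
    if sp > 0:
        best = lcp_at(codes, np.int64(ssa[sp - 1]) * d, q)
    if sp < ssa.shape[0]:
        other = lcp_at(codes, np.int64(ssa[sp]) * d, q)
        if other > best:
            best = other
    return sp, ep, best


@njit(cache=True)
def verified_starts(codes, ssa, d, sp, ep, pat, head_len):
    """Verify the head for each row of a tail hit range.

    ``pat`` is the full (possibly altered) pattern whose tail
    ``pat[head_len:]`` produced rows ``[sp, ep)``. Returns the global
    start positions where the head also matches and the whole window
    fits inside the text.
    """
    n = codes.shape[0]
    m = pat.shape[0]
    out = np.empty(ep - sp, dtype=np.int64)
    cnt = 0
    for r in range(sp, ep):
        s = np.int64(ssa[r]) * d - head_len
        if s < 0 or s + m > n:
            continue
        ok = True
        for j in range(head_len):
            if codes[s + j] != pat[j]:
                ok = False
                break
        if ok:
            out[cnt] = s
            cnt += 1
    return out[:cnt]


@njit(cache=True)
def dfs_align(
    codes,
    ssa,
    d,
    table,
    k_len,
    pat,
    orig,
    head_len,
    level,
    k,
    min_pos,
    alt_stack,
    hits_start,
    hits_mask,
    hits_nmis,
    n_hits,
):
    """Depth-first altered-pattern expansion for one head offset.

    ``pat`` is mutated in place along the tree; ``orig`` is the
    unaltered pattern. New alterations are placed at positions
    ``min_pos <= p <= min(L, m - 1)`` — strictly right of every earlier
    alteration, never beyond the failure prefix L of the current node's
    search — in descending ``p`` with the 3 bases differing from
    ``orig[p]``. A t-mismatch alignment with mismatch set s1 < ... < st
    is reached exactly once, via s1 first: the alignment matches all of
    [0, s1), so s1 <= L at the root, and fixing s1..sj extends the
    matching prefix past s_{j+1} at every step.

    Hits are appended to the output buffers; the returned count may
    exceed the buffer capacity, in which case the caller must retry
    with larger buffers (writes past capacity are suppressed).
    """
    m = pat.shape[0]
    cap = hits_start.shape[0]
    tail = pat[head_len:]
    sp, ep, ltail = search_with_lmp(codes, ssa, d, table, k_len, tail, True)
    if sp < ep:
        n = codes.shape[0]
        for r in range(sp, ep):
            s = np.int64(ssa[r]) * d - head_len
            if s < 0 or s + m > n:
                continue
            ok = True
            for j in range(head_len):
                if codes[s + j] != pat[j]:
                    ok = False
                    break
            if ok:
                if n_hits < cap:
                    hits_start[n_hits] = s
                    hits_nmis[n_hits] = level
                    for t in range(level):
                        hits_mask[n_hits, t] = alt_stack[t]
                n_hits += 1
        fail_prefix = m
    else:
        fail_prefix = head_len + ltail
        if fail_prefix > m:
            fail_prefix = m
    if level < k:
        lim = fail_prefix
        if m - 1 < lim:
            lim = m - 1
        for p in range(lim, min_pos - 1, -1):
            ob = orig[p]
            for c in range(4):
                if c == ob:
                    continue
                pat[p] = np.uint8(c)
                alt_stack[level] = p
                n_hits = dfs_align(
                    codes,
                    ssa,
                    d,
                    table,
                    k_len,
                    pat,
                    orig,
                    head_len,
                    level + 1,
                    k,
                    p + 1,
                    alt_stack,
                    hits_start,
                    hits_mask,
                    hits_nmis,
                    n_hits,
                )
            pat[p] = ob
    return n_hits
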