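"""Rightmost k-mismatch alignment by altered-pattern candidate expansion.

On a failed search the longest matching prefix L of the pattern against
the sampled suffixes bounds where an alteration can possibly help:
positions right of L are pruned. Candidates are expanded level by level
(level j alters exactly j positions), each new alteration strictly
right of the parent's rightmost one and no further than the parent's
failure prefix, which makes every mismatch set reachable exactly once:
for a mismatch set s1 < ... < st the alignment matches everything left
of s1, so s1 lies within the root's failure prefix, and fixing s1..sj
pushes the failure prefix past s_{j+1} at every step. Results are
ordered by the rightmost criteria: the m-bit
number B with 0-bits at mismatch positions, higher B (errors further
right, toward the 3' end) first.

Two engines produce identical results: a pure-Python level-list engine
(the reference implementation) and a compiled depth-first engine used
by default when numba is importable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import ParameterError, PatternError
from .exact import Alignment, resolve_alignment
from .index import SparseIndex
from .reference import encode_query


@dataclass(frozen=True)
class MismatchMask:
    """Mismatch set of an m-base alignment, in read coordinates."""

    m: int
    positions: tuple[int, ...]  # sorted ascending

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ParameterError("mismatch positions must be distinct and ascending")
        if self.positions and not (0 <= self.positions[0] and self.positions[-1] < self.m):
            raise ParameterError("mismatch position outside [0, m)")

    def b_value(self) -> int:
        """The integer B: bit m-1-j is 0 iff position j mismatches."""
        b = (1 << self.m) - 1
        for j in self.positions:
            b -= 1 << (self.m - 1 - j)
        return b


def rightmost_compare(a: MismatchMask, b: MismatchMask) -> int:
    """-1 if ``a`` precedes ``b`` under the rightmost criteria (higher B),
    +1 if it follows, 0 if equal."""
    if a.m != b.m:
        raise ParameterError(f"mask lengths differ: {a.m} != {b.m}")
    ba, bb = a.b_value(), b.b_value()
    if ba > bb:
        return -1
    if ba < bb:
        return 1
    return 0


@dataclass
class Candidate:
    """An altered pattern in the level-expansion tree.

    ``altered_positions`` is the ascending list of read coordinates
    changed so far (its length is the level); ``head_offset`` is the
    head length i of the sparse search this candidate belongs to.
    ``failure_prefix`` is filled in after the candidate's exact search:
    the longest matching prefix on failure, or m on a hit.
    """

    pattern: np.ndarray
    altered_positions: tuple[int, ...]
    head_offset: int
    failure_prefix: int | None = field(default=None, compare=False)

    @property
    def level(self) -> int:
        return len(self.altered_positions)


def longest_matching_prefix(idx: SparseIndex, q: str) -> int:
    """Longest prefix of ``q`` occurring among the sampled suffixes.

    Defined at search failure from the two rows adjacent to the
    binary-search insertion point; returns ``len(q)`` when ``q`` occurs.
    """
    qc = encode_query(q)
    _sp, _ep, lmp = _kernels.search_with_lmp(
        idx.genome.codes, idx.ssa, idx.D, idx.table, idx.K, qc, True
    )
    return int(lmp)


def generate_level_candidates(
    parents: list[Candidate], original: np.ndarray
) -> list[Candidate]:
    """Expand level j-1 candidates into level j, in rightmost order.

    Each parent with failure prefix L' contributes one candidate per
    position p with rightmost previous alteration < p <= min(L', m - 1),
    in descending p, and per base differing from the original read base
    (3 per position). Positions right of L' are pruned: the parent's
    prefix of length L' + 1 occurs nowhere among the sampled suffixes,
    so altering only beyond it cannot produce a match.
    """
    out: list[Candidate] = []
    m = int(original.shape[0])
    for parent in parents:
        if parent.failure_prefix is None:
            raise ParameterError("parent candidate has not been searched yet")
        lim = min(parent.failure_prefix, m - 1)
        low = parent.altered_positions[-1] + 1 if parent.altered_positions else 0
        for p in range(lim, low - 1, -1):
            orig_base = int(original[p])
            for c in range(4):
                if c == orig_base:
                    continue
                pat = parent.pattern.copy()
                pat[p] = c
                out.append(
                    Candidate(pat, parent.altered_positions + (p,), parent.head_offset)
                )
    return out


def _python_engine(idx: SparseIndex, pat: np.ndarray, k: int) -> list[tuple[int, tuple[int, ...]]]:
    """Level-list engine: search every candidate, expand level by level."""
    g = idx.genome
    m = int(pat.shape[0])
    raw: list[tuple[int, tuple[int, ...]]] = []
    for i in range(idx.D):
        parents = [Candidate(pat.copy(), (), i)]
        for level in range(k + 1):
            for cand in parents:
                sp, ep, ltail = _kernels.search_with_lmp(
                    g.codes, idx.ssa, idx.D, idx.table, idx.K, cand.pattern[i:], True
                )
                if sp < ep:
                    for s in _kernels.verified_starts(
                        g.codes, idx.ssa, idx.D, sp, ep, cand.pattern, i
                    ):
                        raw.append((int(s), tuple(sorted(cand.altered_positions))))
                    cand.failure_prefix = m
                else:
                    cand.failure_prefix = min(i + int(ltail), m)
            if level < k:
                parents = generate_level_candidates(parents, pat)
    return raw


def _fast_engine(idx: SparseIndex, pat: np.ndarray, k: int) -> list[tuple[int, tuple[int, ...]]]:
    """Compiled depth-first engine; retries with larger buffers on overflow."""
    g = idx.genome
    m = int(pat.shape[0])
    k_slots = max(k, 1)
    cap = 4096
    raw: list[tuple[int, tuple[int, ...]]] = []
    for i in range(idx.D):
        while True:
            hits_start = np.empty(cap, dtype=np.int64)
            hits_mask = np.empty((cap, k_slots), dtype=np.int64)
            hits_nmis = np.empty(cap, dtype=np.int64)
            alt_stack = np.zeros(k_slots, dtype=np.int64)
            n = _kernels.dfs_align(
                g.codes, idx.ssa, idx.D, idx.table, idx.K,
                pat.copy(), pat, i, 0, k, 0,
                alt_stack, hits_start, hits_mask, hits_nmis, 0,
            )
            if n <= cap:
                break
            cap = max(cap * 2, int(n))
        for t in range(int(n)):
            nm = int(hits_nmis[t])
            raw.append(
                (int(hits_start[t]), tuple(sorted(int(x) for x in hits_mask[t, :nm])))
            )
    return raw


def k_mismatch_align(
    idx: SparseIndex,
    pattern: str,
    k: int,
    *,
    ambiguous: str = "reject",
    engine: str = "auto",
) -> list[tuple[Alignment, MismatchMask]]:
    """All alignments of ``pattern`` with Hamming distance <= k.

    Returns (Alignment, MismatchMask) pairs sorted by the rightmost
    criteria (decreasing B), ties broken by ascending genomic start.
    ``engine`` is one of "auto", "fast", "python".
    """
    if k < 0:
        raise ParameterError(f"mismatch budget must be >= 0, got {k}")
    pat = encode_query(pattern, ambiguous)
    m = int(pat.shape[0])
    if m < idx.D:
        raise PatternError("pattern shorter than sparsification factor")
    if engine == "auto":
        engine = "fast" if _kernels.HAVE_NUMBA else "python"
    if engine == "fast":
        raw = _fast_engine(idx, pat, k)
    elif engine == "python":
        raw = _python_engine(idx, pat, k)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    results: list[tuple[Alignment, MismatchMask]] = []
    for gstart, mask in raw:
        aln = resolve_alignment(idx.genome, gstart, m, mask)
        if aln is not None:
            results.append((aln, MismatchMask(m, mask)))
    results.sort(key=lambda pair: (-pair[1].b_value(), pair[0].gstart))
    return results
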