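"""Exact alignment by head/tail offset decomposition over the SSA.

For each offset i in [0, D) the pattern splits into a head (first i
bases, verified directly against the genome) and a tail (searched on
the sparse suffix array). Every genomic occurrence at start s is found
by exactly one offset, i = (-s) mod D.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _kernels
from .errors import ParameterError, PatternError
from .index import SparseIndex
from .reference import PackedGenome, encode_query


@dataclass(frozen=True)
class SuffixRange:
    """Half-open interval [sp, ep) of SSA rows; empty iff sp == ep."""

    sp: int
    ep: int

    def __post_init__(self) -> None:
        if not 0 <= self.sp <= self.ep:
            raise ParameterError(f"invalid suffix range [{self.sp}, {self.ep})")

    @property
    def is_empty(self) -> bool:
        return self.sp == self.ep

    def __len__(self) -> int:
        return self.ep - self.sp


@dataclass(frozen=True)
class Alignment:
    """A strandless placement of a pattern on one reference record.

    ``start`` is 0-based within the record, ``gstart`` the global
    position on the concatenation. ``mismatch_positions`` are read
    coordinates where the read base differs from the reference;
    ``n_flag`` marks windows overlapping a converted non-ACGT position.
    """

    record: str
    start: int
    gstart: int
    length: int
    mismatch_positions: tuple[int, ...]
    n_flag: bool


def resolve_alignment(
    genome: PackedGenome, gstart: int, length: int, mask: tuple[int, ...]
) -> Alignment | None:
    """Build an Alignment at a verified global start, or None if the
    window would span a record boundary."""
    name, rec_start, rec_len = genome.record_of(gstart)
    offset = gstart - rec_start
    if offset + length > rec_len:
        return None
    return Alignment(
        record=name,
        start=offset,
        gstart=gstart,
        length=length,
        mismatch_positions=mask,
        n_flag=genome.window_has_n(gstart, gstart + length),
    )


def ssa_range_search(
    idx: SparseIndex, q, *, use_table: bool = True, ambiguous: str = "reject"
) -> SuffixRange:
    """Maximal SSA row range whose suffixes have ``q`` as a prefix.

    With ``use_table`` (and ``len(q) >= K``) the search narrows to the
    partition-table interval of the first K bases first; both paths
    return identical ranges.
    """
    qc = q if not isinstance(q, str) else encode_query(q, ambiguous)
    if qc.shape[0] < 1:
        raise PatternError("empty query")
    sp, ep = _kernels.range_search(
        idx.genome.codes, idx.ssa, idx.D, idx.table, idx.K, qc, use_table
    )
    return SuffixRange(int(sp), int(ep))


def verify_head(
    idx: SparseIndex, tail_start: int, head: str, pattern_length: int
) -> Alignment | None:
    """Check that ``head`` precedes ``tail_start`` in the genome.

    ``tail_start`` must be a sampled position (D times an SSA entry).
    Returns an exact Alignment anchored at ``tail_start - len(head)``
    when the head matches, the start is in range, and the full
    ``pattern_length`` window stays inside one record; otherwise None.
    """
    head_codes = encode_query(head) if head else None
    i = len(head)
    if not 0 <= i < idx.D and idx.D > 1:
        raise ParameterError(f"head length {i} outside [0, {idx.D})")
    start = tail_start - i
    if start < 0 or start + pattern_length > idx.genome.n:
        return None
    if head_codes is not None:
        if not (idx.genome.codes[start : start + i] == head_codes).all():
            return None
    return resolve_alignment(idx.genome, start, pattern_length, ())


def exact_align(idx: SparseIndex, pattern: str, *, ambiguous: str = "reject") -> list[Alignment]:
    """All exact occurrences of ``pattern``, sorted by start position.

    Runs one tail search per offset i in [0, D) and verifies each hit's
    head directly against the genome.
    """
    pat = encode_query(pattern, ambiguous)
    m = pat.shape[0]
    if m < idx.D:
        raise PatternError("pattern shorter than sparsification factor")
    g = idx.genome
    hits: list[Alignment] = []
    for i in range(idx.D):
        sp, ep = _kernels.range_search(g.codes, idx.ssa, idx.D, idx.table, idx.K, pat[i:], True)
        if sp == ep:
            continue
        for s in _kernels.verified_starts(g.codes, idx.ssa, idx.D, sp, ep, pat, i):
            aln = resolve_alignment(g, int(s), m, ())
            if aln is not None:
                hits.append(aln)
    hits.sort(key=lambda a: (a.gstart, len(a.mismatch_positions)))
    return hits
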