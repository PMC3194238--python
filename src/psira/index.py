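"""Sparse suffix array index: construction, partition table, serialization.

The index has two parts: the 2-bit packed genome and the sparse suffix
array (suffix start positions divisible by D, stored divided by D, in
lexicographic suffix order), plus a 4^K-row partition table mapping each
K-mer to its half-open row interval on the SSA.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .errors import (
    BadMagicError,
    ParameterError,
    TruncatedIndexError,
    UnsupportedVersionError,
)
from .reference import PackedGenome

MAGIC = b"PSIRA1"
FORMAT_VERSION = 1

#: Largest permitted 4^K (table rows); K beyond this is rejected.
MAX_TABLE_ROWS = 1 << 24


@dataclass(frozen=True)
class SuffixArray:
    """Full suffix array: entry i is the start of the i-th smallest suffix."""

    entries: np.ndarray

    def __len__(self) -> int:
        return int(self.entries.shape[0])


@dataclass
class SparseIndex:
    """Searchable index: genome + SSA + K-mer partition table."""

    genome: PackedGenome
    D: int
    K: int
    ssa: np.ndarray  # uint32, suffix starts divided by D, in suffix order
    table: np.ndarray  # uint32 (4^K, 2), half-open SSA row intervals

    def __len__(self) -> int:
        return int(self.ssa.shape[0])

    @property
    def table_occupancy(self) -> int:
        """Number of K-mers with a non-empty row interval."""
        return int(np.count_nonzero(self.table[:, 1] > self.table[:, 0]))


def build_suffix_array(genome: PackedGenome) -> SuffixArray:
    """Suffix array of the sentinel-terminated genome (prefix doubling).

    Shorter suffixes sort before longer ones sharing a prefix, encoding
    the implicit end-of-text sentinel.
    """
    n = genome.n
    if n < 1:
        raise ParameterError("no sequence")
    rank = genome.codes.astype(np.int64)
    step = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - step] = rank[step:]
        sa = np.lexsort((key2, rank))
        r1 = rank[sa]
        r2 = key2[sa]
        changed = np.empty(n, dtype=bool)
        changed[0] = False
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = np.cumsum(changed)
        if rank[sa[-1]] == n - 1:
            return SuffixArray(sa.astype(np.int64))
        step *= 2


def sparsify(sa: SuffixArray, d: int) -> np.ndarray:
    """Keep entries divisible by ``d`` (order preserved), divided by ``d``."""
    if d < 1:
        raise ParameterError(f"sparsification factor must be >= 1, got {d}")
    entries = sa.entries
    return (entries[entries % d == 0] // d).astype(np.int64)


def _row_prefix_keys(genome: PackedGenome, ssa: np.ndarray, d: int, k: int) -> np.ndarray:
    """Sortable K-prefix key per SSA row: 3 bits per base, sentinel = 0."""
    n = genome.n
    codes = genome.codes
    pos = ssa.astype(np.int64) * d
    keys = np.zeros(ssa.shape[0], dtype=np.int64)
    for j in range(k):
        pj = pos + j
        in_range = pj < n
        v = np.where(in_range, codes[np.minimum(pj, n - 1)].astype(np.int64) + 1, 0)
        keys |= v << (3 * (k - 1 - j))
    return keys


def _kmer_keys(k: int) -> np.ndarray:
    """Key of every K-mer code 0..4^K-1 under the same 3-bit packing."""
    cs = np.arange(4**k, dtype=np.int64)
    keys = np.zeros_like(cs)
    for j in range(k):
        digit = (cs >> (2 * (k - 1 - j))) & 3
        keys |= (digit + 1) << (3 * (k - 1 - j))
    return keys


def build_partition_table(
    genome: PackedGenome, ssa: np.ndarray, d: int, k: int
) -> np.ndarray:
    """Half-open SSA row interval per K-mer, as a (4^K, 2) uint32 array.

    Sampled suffixes shorter than K bases sort (sentinel-first) at the
    head of their prefix group and belong to no K-mer interval; for a
    K-mer absent from every sampled suffix both bounds equal the
    insertion point of that K-mer among the rows, so the table path of a
    range search still lands on the global binary-search position.
    """
    if k < 1:
        raise ParameterError(f"partition prefix length must be >= 1, got {k}")
    if 4**k > MAX_TABLE_ROWS:
        raise ParameterError(
            f"4^{k} rows exceed the table budget ({MAX_TABLE_ROWS}); use a smaller K"
        )
    row_keys = _row_prefix_keys(genome, ssa, d, k)
    kmer_keys = _kmer_keys(k)
    lo = np.searchsorted(row_keys, kmer_keys, side="left")
    hi = np.searchsorted(row_keys, kmer_keys, side="right")
    return np.column_stack([lo, hi]).astype(np.uint32)


def build_index(genome: PackedGenome, d: int = 4, k: int = 8) -> SparseIndex:
    """Compose suffix-array construction, sparsification and the table."""
    if d < 1:
        raise ParameterError(f"sparsification factor must be >= 1, got {d}")
    n_entries = -(-genome.n // d)  # ceil
    if n_entries >= 1 << 32:
        raise ParameterError("sparse suffix array does not fit 32-bit cells")
    sa = build_suffix_array(genome)
    ssa = sparsify(sa, d).astype(np.uint32)
    table = build_partition_table(genome, ssa, d, k)
    return SparseIndex(genome=genome, D=d, K=k, ssa=ssa, table=table)


# --- serialization -----------------------------------------------------------

_HEADER = struct.Struct("<6sHQIIIQI")  # magic, version, n, D, K, nrec, npos, nssa


def _pack_codes(codes: np.ndarray) -> bytes:
    pad = (-codes.shape[0]) % 4
    c = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)]).reshape(-1, 4)
    packed = c[:, 0] | (c[:, 1] << 2) | (c[:, 2] << 4) | (c[:, 3] << 6)
    return packed.astype(np.uint8).tobytes()


def _unpack_codes(buf: bytes, n: int) -> np.ndarray:
    b = np.frombuffer(buf, dtype=np.uint8)
    out = np.empty((b.shape[0], 4), dtype=np.uint8)
    out[:, 0] = b & 3
    out[:, 1] = (b >> 2) & 3
    out[:, 2] = (b >> 4) & 3
    out[:, 3] = (b >> 6) & 3
    return out.reshape(-1)[:n].copy()


def save_index(idx: SparseIndex) -> bytes:
    """Serialize to the little-endian PSIRA1 blob format."""
    g = idx.genome
    parts = [
        _HEADER.pack(
            MAGIC,
            FORMAT_VERSION,
            g.n,
            idx.D,
            idx.K,
            len(g.records),
            g.n_positions.shape[0],
            idx.ssa.shape[0],
        )
    ]
    for name, start, length in g.records:
        raw = name.encode("utf-8")
        parts.append(struct.pack("<H", len(raw)))
        parts.append(raw)
        parts.append(struct.pack("<QQ", start, length))
    parts.append(g.n_positions.astype("<u4").tobytes())
    parts.append(_pack_codes(g.codes))
    parts.append(idx.ssa.astype("<u4").tobytes())
    parts.append(idx.table.astype("<u4").tobytes())
    return b"".join(parts)


class _Cursor:
    def __init__(self, data: bytes) -> None:
        self.data = data
        self.pos = 0

    def take(self, nbytes: int) -> bytes:
        if self.pos + nbytes > len(self.data):
            raise TruncatedIndexError(
                f"index blob truncated: need {self.pos + nbytes} bytes, have {len(self.data)}"
            )
        out = self.data[self.pos : self.pos + nbytes]
        self.pos += nbytes
        return out


def load_index(data: bytes) -> SparseIndex:
    """Inverse of :func:`save_index`; raises distinct errors on bad blobs."""
    cur = _Cursor(data)
    header = cur.take(_HEADER.size)
    magic, version, n, d, k, nrec, npos, nssa = _HEADER.unpack(header)
    if magic != MAGIC:
        raise BadMagicError(f"bad magic {magic!r}, expected {MAGIC!r}")
    if version != FORMAT_VERSION:
        raise UnsupportedVersionError(f"unsupported index version {version}")
    records: list[tuple[str, int, int]] = []
    for _ in range(nrec):
        (name_len,) = struct.unpack("<H", cur.take(2))
        name = cur.take(name_len).decode("utf-8")
        start, length = struct.unpack("<QQ", cur.take(16))
        records.append((name, start, length))
    n_positions = np.frombuffer(cur.take(4 * npos), dtype="<u4").astype(np.int64)
    codes = _unpack_codes(cur.take((n + 3) // 4), n)
    ssa = np.frombuffer(cur.take(4 * nssa), dtype="<u4").astype(np.uint32)
    table = (
        np.frombuffer(cur.take(4 * 2 * 4**k), dtype="<u4")
        .astype(np.uint32)
        .reshape(4**k, 2)
    )
    genome = PackedGenome(codes, records, n_positions)
    return SparseIndex(genome=genome, D=d, K=k, ssa=ssa.copy(), table=table.copy())
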