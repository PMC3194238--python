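"""2-bit packed reference genomes with a global coordinate map.

A multi-record FASTA reference is concatenated into one code array
(A=0, C=1, G=2, T=3). A single logical sentinel terminates the whole
concatenation; it is never stored, suffix comparisons simply treat
"past the end" as smaller than any base. Record boundaries are kept so
alignments can be reported in per-record coordinates and windows that
would span two records can be discarded.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .errors import AmbiguousBaseError, EncodingError

#: Character used to display the implicit end-of-text sentinel.
SENTINEL = "$"

_DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

# 255 = letter outside {A,C,G,T}; applied after upper-casing.
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i


def _to_upper(arr: np.ndarray) -> np.ndarray:
    lower = (arr >= ord("a")) & (arr <= ord("z"))
    return np.where(lower, arr - 32, arr)


@dataclass
class PackedGenome:
    """Concatenated reference in 2-bit code.

    Parameters
    ----------
    codes : numpy.ndarray
        uint8 array of values 0..3, one per base of the concatenation.
    records : list of (name, global start, length)
        Record intervals, in input order; disjoint, contiguous, covering
        ``[0, n)``.
    n_positions : numpy.ndarray
        Sorted global positions whose original character was not A/C/G/T
        (stored as code 0, i.e. decoded back as ``A``).
    """

    codes: np.ndarray
    records: list[tuple[str, int, int]]
    n_positions: np.ndarray
    _starts: np.ndarray = field(init=False, repr=False)
    _by_name: dict[str, tuple[int, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint8)
        self.n_positions = np.ascontiguousarray(self.n_positions, dtype=np.int64)
        self._starts = np.array([s for _, s, _ in self.records], dtype=np.int64)
        self._by_name = {name: (start, length) for name, start, length in self.records}

    @property
    def n(self) -> int:
        """Total base count of the concatenation."""
        return int(self.codes.shape[0])

    def decode(self, start: int = 0, end: int | None = None) -> str:
        """Return the nucleotide string for the half-open slice [start, end)."""
        if end is None:
            end = self.n
        return _DECODE_LUT[self.codes[start:end]].tobytes().decode("ascii")

    def base_at(self, p: int) -> str:
        """Base at global position ``p``; ``p == n`` addresses the sentinel."""
        if p < 0 or p > self.n:
            raise IndexError(f"position {p} outside [0, {self.n}]")
        if p == self.n:
            return SENTINEL
        return chr(_DECODE_LUT[self.codes[p]])

    def to_global(self, name: str, offset: int) -> int:
        """Map a (record name, 0-based offset) pair to a global position."""
        try:
            start, length = self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown record {name!r}") from None
        if offset < 0 or offset >= length:
            raise IndexError(f"offset {offset} outside record {name!r} of length {length}")
        return start + offset

    def to_record(self, p: int) -> tuple[str, int]:
        """Map a global position to (record name, 0-based offset)."""
        if p < 0 or p >= self.n:
            raise IndexError(f"position {p} outside [0, {self.n})")
        i = bisect_right(self._starts, p) - 1
        name, start, _length = self.records[i]
        return name, p - start

    def record_of(self, p: int) -> tuple[str, int, int]:
        """Record tuple (name, start, length) containing global position ``p``."""
        if p < 0 or p >= self.n:
            raise IndexError(f"position {p} outside [0, {self.n})")
        return self.records[bisect_right(self._starts, p) - 1]

    def window_has_n(self, start: int, end: int) -> bool:
        """True if any converted non-ACGT position falls inside [start, end)."""
        lo = int(np.searchsorted(self.n_positions, start, side="left"))
        return lo < self.n_positions.shape[0] and int(self.n_positions[lo]) < end


def encode_reference(fasta_records: list[tuple[str, str]]) -> PackedGenome:
    """Pack FASTA records into a :class:`PackedGenome`.

    Lowercase is folded to uppercase. Any letter outside {A,C,G,T}
    (IUPAC ambiguity codes, N, U, ...) is stored as code 0 and its global
    position recorded in ``n_positions``. Non-letter characters are an
    error naming the offending record and position.
    """
    if not fasta_records:
        raise EncodingError("no sequence")
    parts: list[np.ndarray] = []
    records: list[tuple[str, int, int]] = []
    n_positions: list[np.ndarray] = []
    offset = 0
    for name, seq in fasta_records:
        if not seq:
            raise EncodingError("no sequence")
        raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
        upper = _to_upper(raw)
        is_letter = (upper >= ord("A")) & (upper <= ord("Z"))
        if not is_letter.all():
            at = int(np.flatnonzero(~is_letter)[0])
            raise EncodingError(
                f"non-letter character {seq[at]!r} in record {name!r} at position {at}"
            )
        codes = _ENCODE_LUT[upper]
        bad = np.flatnonzero(codes == 255)
        if bad.size:
            n_positions.append(bad.astype(np.int64) + offset)
            codes = codes.copy()
            codes[bad] = 0
        parts.append(codes)
        records.append((name, offset, len(seq)))
        offset += len(seq)
    npos = (
        np.concatenate(n_positions) if n_positions else np.empty(0, dtype=np.int64)
    )
    return PackedGenome(np.concatenate(parts), records, npos)


def encode_query(pattern: str, ambiguous: str = "reject") -> np.ndarray:
    """Encode a query pattern to a uint8 code array.

    ``ambiguous`` controls non-ACGT letters: ``"reject"`` raises
    :class:`AmbiguousBaseError`, ``"substitute"`` maps them to A.
    """
    raw = np.frombuffer(pattern.encode("ascii", errors="replace"), dtype=np.uint8)
    upper = _to_upper(raw)
    is_letter = (upper >= ord("A")) & (upper <= ord("Z"))
    if not is_letter.all():
        at = int(np.flatnonzero(~is_letter)[0])
        raise EncodingError(f"non-letter character {pattern[at]!r} at position {at}")
    codes = _ENCODE_LUT[upper]
    bad = np.flatnonzero(codes == 255)
    if bad.size:
        if ambiguous == "reject":
            raise AmbiguousBaseError(
                f"ambiguous base {pattern[int(bad[0])]!r} at position {int(bad[0])}"
            )
        if ambiguous != "substitute":
            raise ValueError(f"unknown ambiguous-base policy {ambiguous!r}")
        codes = codes.copy()
        codes[bad] = 0
    return np.ascontiguousarray(codes)


def decode_codes(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_query` for valid code arrays."""
    return _DECODE_LUT[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")
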