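"""Deterministic synthetic data and brute-force oracles.

Everything here is a pure function of (input, seed). The oracles
implement the definitions directly — suffix sort over explicit suffix
strings, naive O(nm) scans — and serve as ground truth for the index
and the search modules. Read simulation uses a position-dependent
substitution profile that grows toward the 3' end, where sequencing
errors are more likely.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .index import SuffixArray
from .io import ReadRecord
from .reference import PackedGenome, decode_codes, encode_query


@dataclass(frozen=True)
class LinearErrorProfile:
    """Per-position substitution probability, linear from 5' to 3'."""

    p_start: float = 0.0
    p_end: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_start <= self.p_end <= 1.0:
            raise ParameterError(
                "error profile must satisfy 0 <= p_start <= p_end <= 1 "
                f"(got {self.p_start}, {self.p_end})"
            )

    def probabilities(self, length: int) -> np.ndarray:
        if length == 1:
            return np.array([self.p_start], dtype=float)
        return np.linspace(self.p_start, self.p_end, length)


def generate_genome(n: int, seed: int, name: str = "chr1") -> PackedGenome:
    """i.i.d. uniform ACGT genome of length n, one record."""
    if n < 1:
        raise ParameterError(f"genome length must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=n, dtype=np.int64).astype(np.uint8)
    return PackedGenome(codes, [(name, 0, n)], np.empty(0, dtype=np.int64))


def sample_reads(
    genome: PackedGenome,
    count: int,
    length: int,
    profile: LinearErrorProfile | None,
    seed: int,
) -> list[tuple[ReadRecord, int, tuple[int, ...]]]:
    """Reads from uniform random starts with profile-driven substitutions.

    Returns (read, truth global start, injected mismatch mask) triples.
    Starts are drawn so reads never span a record boundary.
    """
    valid: list[tuple[int, int]] = []  # (record global start, number of valid starts)
    for _name, start, rec_len in genome.records:
        if rec_len >= length:
            valid.append((start, rec_len - length + 1))
    total = sum(c for _, c in valid)
    if total == 0:
        raise ParameterError(f"read length {length} exceeds every record")
    bounds = np.cumsum([c for _, c in valid])
    rng = np.random.default_rng(seed)
    probs = profile.probabilities(length) if profile is not None else np.zeros(length)
    out: list[tuple[ReadRecord, int, tuple[int, ...]]] = []
    picks = rng.integers(0, total, size=count)
    for ridx in range(count):
        pick = int(picks[ridx])
        rec = int(np.searchsorted(bounds, pick, side="right"))
        start = valid[rec][0] + pick - (int(bounds[rec - 1]) if rec else 0)
        codes = genome.codes[start : start + length].copy()
        err_at = np.flatnonzero(rng.random(length) < probs)
        for p in err_at:
            codes[p] = (codes[p] + rng.integers(1, 4)) % 4
        out.append(
            (
                ReadRecord(f"read{ridx}", decode_codes(codes), "I" * length),
                start,
                tuple(int(p) for p in err_at),
            )
        )
    return out


# --- oracles -----------------------------------------------------------------


def oracle_suffix_sort(genome: PackedGenome) -> SuffixArray:
    """Suffix array by explicitly sorting suffix strings (small n only).

    Python string comparison makes a proper prefix sort before its
    extensions, which is exactly the sentinel rule.
    """
    s = genome.decode()
    order = sorted(range(len(s)), key=lambda i: s[i:])
    return SuffixArray(np.array(order, dtype=np.int64))


def oracle_sparse_sort(genome: PackedGenome, d: int) -> np.ndarray:
    """Sparse entries by sorting only the sampled suffixes directly."""
    if d < 1:
        raise ParameterError(f"sparsification factor must be >= 1, got {d}")
    s = genome.decode()
    sampled = sorted(range(0, len(s), d), key=lambda i: s[i:])
    return np.array([p // d for p in sampled], dtype=np.int64)


def oracle_naive_scan(genome: PackedGenome, pattern: str) -> list[int]:
    """Global starts of every exact occurrence, scanning record by record."""
    out: list[int] = []
    for _name, start, rec_len in genome.records:
        text = genome.decode(start, start + rec_len)
        at = text.find(pattern)
        while at != -1:
            out.append(start + at)
            at = text.find(pattern, at + 1)
    return out


def oracle_hamming_scan(
    genome: PackedGenome, pattern: str, k: int
) -> set[tuple[int, tuple[int, ...]]]:
    """Every (global start, mismatch mask) with Hamming distance <= k,
    windows confined to single records."""
    pat = encode_query(pattern)
    m = pat.shape[0]
    out: set[tuple[int, tuple[int, ...]]] = set()
    for _name, start, rec_len in genome.records:
        if rec_len < m:
            continue
        arr = genome.codes[start : start + rec_len]
        windows = np.lib.stride_tricks.sliding_window_view(arr, m)
        mism = windows != pat[None, :]
        counts = mism.sum(axis=1)
        for s in np.flatnonzero(counts <= k):
            mask = tuple(int(p) for p in np.flatnonzero(mism[s]))
            out.add((start + int(s), mask))
    return out


def write_fixture_files(
    directory: str,
    genome: PackedGenome,
    reads: list[tuple[ReadRecord, int, tuple[int, ...]]],
) -> dict[str, str]:
    """Emit ref.fa, reads.fq and truth.tsv for end-to-end CLI tests."""
    paths = {
        "reference": os.path.join(directory, "ref.fa"),
        "reads": os.path.join(directory, "reads.fq"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    with open(paths["reference"], "w") as fh:
        for name, start, length in genome.records:
            fh.write(f">{name}\n")
            seq = genome.decode(start, start + length)
            for at in range(0, length, 70):
                fh.write(seq[at : at + 70] + "\n")
    with open(paths["reads"], "w") as fh:
        for read, _start, _mask in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("read_id\tstart\tmask\n")
        for read, start, mask in reads:
            fh.write(f"{read.id}\t{start}\t{','.join(map(str, mask))}\n")
    return paths
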