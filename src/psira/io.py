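"""Read input (FASTA/FASTQ) and alignment output (SAM/TSV)."""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

from .errors import ParameterError
from .exact import Alignment
from .mismatch import MismatchMask
from .reference import PackedGenome

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; quality is carried through, never scored."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParameterError(f"read {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParameterError(f"read {self.id!r}: quality length != sequence length")


@dataclass(frozen=True)
class Hit:
    """One reported placement of a read."""

    alignment: Alignment
    mask: MismatchMask
    strand: str  # '+' or '-'


@dataclass
class ReadResult:
    """All hits for one read, already in rightmost order; or the reason
    the read could not be aligned."""

    read: ReadRecord
    hits: list[Hit]
    unaligned_reason: str | None = None


def read_fasta_reference(path: str) -> list[tuple[str, str]]:
    """Multi-record FASTA; record name = first whitespace token of the header."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    return records


def read_reads(path: str) -> list[ReadRecord]:
    """FASTA or FASTQ reads, auto-detected from the first character."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        out = []
        for rec in SeqIO.parse(path, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append(ReadRecord(rec.id, str(rec.seq), qual))
        return out
    if first == ">":
        return [ReadRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    raise ParameterError(f"cannot detect read format of {path!r} (first char {first!r})")


def _sam_seq_qual(result: ReadResult, strand: str) -> tuple[str, str]:
    seq = result.read.sequence
    qual = result.read.quality or "*"
    if strand == "-":
        seq = reverse_complement(seq)
        if qual != "*":
            qual = qual[::-1]
    return seq, qual


def write_sam(results: list[ReadResult], genome: PackedGenome, program_version: str) -> str:
    """SAM 1.x text: @HD/@SQ from the record table, one line per hit,
    FLAG 4 for unaligned reads, 256 for secondary hits, 16 for reverse
    strand. NM = mismatch count; XB = comma-joined mismatch read
    positions (omitted for exact hits); XN:i:1 flags windows that
    overlap a converted non-ACGT reference position."""
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, _start, length in genome.records:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.append(f"@PG\tID:psira\tPN:psira\tVN:{program_version}")
    for result in results:
        if not result.hits:
            reason = result.unaligned_reason or "no_alignment"
            qual = result.read.quality or "*"
            lines.append(
                f"{result.read.id}\t4\t*\t0\t0\t*\t*\t0\t0\t"
                f"{result.read.sequence}\t{qual}\tXR:Z:{reason}"
            )
            continue
        for rank, hit in enumerate(result.hits):
            flag = 0
            if rank > 0:
                flag |= 256
            if hit.strand == "-":
                flag |= 16
            aln = hit.alignment
            seq, qual = _sam_seq_qual(result, hit.strand)
            fields = [
                result.read.id,
                str(flag),
                aln.record,
                str(aln.start + 1),
                "255",
                f"{aln.length}M",
                "*",
                "0",
                "0",
                seq,
                qual,
                f"NM:i:{len(aln.mismatch_positions)}",
            ]
            if aln.mismatch_positions:
                fields.append("XB:Z:" + ",".join(map(str, aln.mismatch_positions)))
            if aln.n_flag:
                fields.append("XN:i:1")
            lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def write_tsv(results: list[ReadResult]) -> str:
    """TSV: read_id, record, start0, strand, mismatch_count,
    mismatch_positions (comma-joined, empty for exact), n_flag.
    Unaligned reads get record '*' and the reason in the last column."""
    lines = ["read_id\trecord\tstart0\tstrand\tmismatch_count\tmismatch_positions\tn_flag"]
    for result in results:
        if not result.hits:
            reason = result.unaligned_reason or "no_alignment"
            lines.append(f"{result.read.id}\t*\t-1\t.\t-1\t{reason}\t0")
            continue
        for hit in result.hits:
            aln = hit.alignment
            positions = ",".join(map(str, aln.mismatch_positions))
            lines.append(
                f"{result.read.id}\t{aln.record}\t{aln.start}\t{hit.strand}\t"
                f"{len(aln.mismatch_positions)}\t{positions}\t{int(aln.n_flag)}"
            )
    return "\n".join(lines) + "\n"
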