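# psira

Sparse suffix array (SSA) indexing and alignment of short DNA reads, with
exact search by head/tail offset decomposition and rightmost *k*-mismatch
approximate search.

The index samples the suffix array at positions divisible by a
sparsification factor `D` (storing each start divided by `D`), trading
index size (`ceil(n/D)` 32-bit entries) against `D` offset searches per
query. A `4^K`-row partition table maps each `K`-mer prefix to its SSA
row interval, shrinking each binary search. Approximate alignment
expands altered patterns level by level, pruning with the longest
matching prefix `L` obtained from the binary-search insertion point on
failure, and reports alignments ordered by the rightmost criteria: the
*m*-bit number `B` with 0-bits at mismatch positions, higher `B`
(mismatches nearer the 3' end, where sequencing errors concentrate)
first.

## Layout

| module | contents |
| --- | --- |
| `psira.reference` | 2-bit packed genome, non-ACGT bookkeeping, coordinate map |
| `psira.index` | suffix array, sparsification, partition table, `PSIRA1` (de)serialization |
| `psira.exact` | range search, head verification, exact alignment over all offsets |
| `psira.mismatch` | failure-prefix computation, candidate expansion, rightmost *k*-mismatch alignment |
| `psira.io` / `psira.cli` | FASTA/FASTQ input, SAM/TSV output, `index`/`align` commands |
| `psira.fixtures` | seeded synthetic genomes/reads and brute-force oracles |
| `psira._kernels` | hot search loops (JIT-compiled via numba when available, plain Python otherwise) |

## CLI

```sh
psira index --ref ref.fa --sparse 4 --kmer 8 --out ref.psira
psira align --index ref.psira --reads reads.fq --mismatches 2 \
            --threads 4 --format sam --out out.sam
```

`align` auto-detects FASTQ/FASTA reads, emits every hit per read in
rightmost order (`--max-hits N` truncates after sorting), always reports
unaligned reads (FLAG 4 with a reason tag), and maps the forward strand
only unless `--both-strands` is given (reverse hits get FLAG 16).
Reads are partitioned across worker processes; any `--threads` value
produces byte-identical output. SAM lines carry `NM` (mismatch count),
`XB` (comma-joined mismatch read positions) and `XN:i:1` when the
window overlaps a reference position that was not A/C/G/T.

## Library example

```python
from psira import build_index, encode_reference, k_mismatch_align

idx = build_index(encode_reference([("chr1", "AGGTCGATTCGGGACC")]), d=4, k=1)
for aln, mask in k_mismatch_align(idx, "GGTCGATTCGGGACC", 1):
    print(aln.record, aln.start, mask.positions)
```

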