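# refqz

Lossless reference-based compression of FASTQ files.

Raw sequencing output in FASTQ format is dominated by three very different
kinds of text — record headers, nucleotide reads, and per-base quality
strings — and a general-purpose compressor treats them all the same. `refqz`
splits the file into those three streams and removes the redundancy of each
with a scheme matched to its structure, then packs the results with LZMA.
Decompression with the same reference reproduces the input **byte for byte**:
no trimming, no reordering, no quality quantization.

It is aimed at anyone archiving or shipping FASTQ data for which a homologous
reference genome exists: the reference is *not* stored in the archive, only a
checksum that turns a wrong-reference mistake into a clean error.

## How it works

**Headers** are coded incrementally. A header such as
`@SRR001471.2 E96DJWM01CO1KR length = 297` is reduced to the diff against its
predecessor: the running record number is implied by position, the
`length = n` token is implied by the read itself, and the informative field is
stored as `(common-prefix length, suffix)` — here `9 CO1KR`.

**Reads** are stored as alignments against an external reference *R* found by
a light-weight mapping model. An index *I_R* holds the positions of every
k-mer of *R* prefixed by the dimer `CG` (the most common dimer; indexing only
these keeps the table small), keyed by the 2-bit packing A=00, C=01, G=10,
T=11 — e.g. `CGATT` → `0110001111`. Each indexed k-mer of a read at offset
*i* votes for candidate start position *I_R⟨K#⟩ − i*; the modal candidate POS
seeds a greedy base-by-base alignment that classifies columns as
M/I/D/S (match / insertion / deletion / substitution) and stops when the
running mismatch fraction would exceed *e*. A read is then stored as
`[POS] <PAL> [MLength]<MType><MisValues>`, e.g. `12 7M2D5M`. If only a prefix
aligns, the reverse complement of the remainder is sent through the mapper
once more (palindrome re-entry, flagged `0`); whatever still fails is stored
verbatim with POS = 0. Every mapping is verified by reconstruction, and
residual differences are appended as delta-coded corrections (`16A7C` = fix
position 16 to A, then position 16+7 to C), so losslessness never depends on
alignment quality. Defaults: k = 10, minimum aligned length L = 12, mismatch
rate e = 0.05.

**Qualities** use run-length-limited coding: any run of n > 2 equal
characters becomes the character with its 8th bit set plus one length byte
(n ≤ 256; longer runs are split), so `CCCGFFFFFFFHH` → `Ĉ3 G F̂7 H H`.
Blocks of ≥ 4 runs alternating between two characters are further shortened
by dropping the interior characters: `DDDDCCCDDDDDCCCC` goes from 8 coded
symbols to 6 (`D̂4 3 5 Ĉ4`).

## Worked example

The bundled simulator generates a reference, a corpus of reads sampled from
it (1% substitutions, 0.1% indels by default) with run-rich qualities and
454-style headers, plus a ground-truth table:

```sh
$ refqz simulate --seed 7 -o demo --n-reads 2000 --read-length 100 --ref-length 50000
wrote 2000 records to demo

$ refqz compress -i demo/reads.fastq -r demo/reference.fa -o demo/reads.rfqz
2000 records (1831 mapped, 169 raw): 494893 -> 61261 bytes (ratio 0.124)

$ refqz stats demo/reads.rfqz
records: 2000  reference: 50000 bases (crc32 cc7054f2)
params: k=10 L=12 e=0.05
  metadata:         7672 bytes (12.5% of archive)
     reads:        23348 bytes (38.1% of archive)
 qualities:        30180 bytes (49.3% of archive)

$ refqz decompress -i demo/reads.rfqz -r demo/reference.fa -o demo/round.fastq
wrote 494893 bytes to demo/round.fastq

$ cmp demo/reads.fastq demo/round.fastq && echo IDENTICAL
IDENTICAL
```

The compression ratio (compressed size ÷ original size, smaller is better)
here is 0.124: the archive is an eighth of the input. "169 raw" counts reads
stored verbatim — this corpus deliberately includes unmappable and
reverse-complemented reads. Quality scores dominate the archive, as their
larger alphabet and noisier distribution make them the hardest stream to
compress.

The same operations are available as a library (`refqz.compress_bytes`,
`refqz.map_read`, `refqz.quality_codec.rll_encode`, …); see `docs/methods.md`
for the model details and design notes.

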