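# Methods

This note records the model behind `refqz`, the parameters that matter, the
numerical and format choices that were genuinely open, and what the synthetic
test corpora do and do not demonstrate.

## Stream separation

A FASTQ record's four lines carry three statistically unrelated payloads:
free-text metadata, a nucleotide read over a 5-letter alphabet, and a quality
string over ~40 printable characters with strong local repetition. Each
stream is encoded independently and the three encoded payloads are compressed
separately with LZMA (preset 6, fixed in the format for reproducibility) and
concatenated behind a small binary header. Per-stream compression was chosen
over one joint LZMA pass so a payload can be located and inspected without
decoding the others; LZMA's dictionary is large relative to our payloads, so
the cost of splitting is negligible.

The separator ("plus") line is a single flag when every record uses a bare
`+`; otherwise all plus lines travel verbatim in the metadata payload.
Line terminators are recorded as one global style plus a per-line exception
list (including a "no terminator" marker for a final line without a newline),
which keeps the byte-exact round trip even for mixed-terminator files rather
than rejecting them.

## Header codec

Headers are tokenized on single spaces. From the first header a template is
derived (first token minus its trailing number, required to be 1); each later
record is coded in the cheapest mode that reproduces it exactly:

* **A** — first token equals `<template><ordinal>` and the header ends in
  `length = <read length>`: both are elided, and the remaining informative
  field is stored as `(common prefix length vs. previous field, suffix)`.
* **B** — template matches but no (or a non-matching) length token: the whole
  remainder after the first token is prefix-diff coded.
* **D** — whole-line prefix diff (Illumina-style colon ids, tabs, doubled
  spaces, anything untemplated).
* **V** — verbatim (first record, pathological lines).

Diffing is always against the immediately preceding record, never a global
model. The decoder re-derives its "previous field" state from each decoded
header using the same extraction function as the encoder, so the two state
machines cannot drift apart. Read lengths are supplied by the read-stream
decoder at decompression time; the `length = n` token is only elided when its
value equals the actual read length, otherwise it is kept.

## Read mapping model

The reference is normalized (uppercase; every non-ACGT code, including IUPAC
ambiguity letters, becomes N) and indexed once: every k-mer starting with the
dimer `CG` and free of N is stored under its 2-bit key (A=00, C=01, G=10,
T=11) with its 1-based positions. Restricting seeds to one common dimer
shrinks the table ~16-fold at some cost in sensitivity; reads without any
indexed seed are simply stored raw, which costs space but never correctness.
k is capped at 16 so keys stay within a machine word; the default k = 10,
together with minimum aligned length L = 12 and mismatch budget e = 0.05,
follows the tool's standard parameterization.

Mapping a read: every indexed k-mer at read offset *i* votes for candidate
position `p − i`; the candidate with most votes wins. On a vote tie, a local
alignment is run at every tied candidate and the one with the most matched
bases is kept, remaining ties going to the smallest position, so output is
deterministic.

The local alignment is greedy and base-by-base. At a mismatch it probes a
substitution and insertion/deletion gaps of 1..5 bases, scoring each by how
many of the following 8 bases re-synchronize (tie order: S, then D, then I;
shorter gaps first), and stops before the running mismatch fraction
(S+I+D columns over all columns consumed) would exceed e. Trailing non-match
events are trimmed so an alignment always ends on a match. This is not an
optimal edit-distance alignment and does not need to be: the verification
pass reconstructs the read from the mapping and appends delta-coded
corrections for any residual difference, so a poor alignment only costs
bytes. A reconstruction of the wrong *length* indicates a bug and is a hard
error, never patched silently. Correction positions are read coordinates
(first absolute, then successive offsets).

When the alignment covers only a prefix, the reverse complement of the
remainder re-enters the mapper once (reads spanning inverted repeats or
sequenced from the other strand map this way); the re-entry is flagged and
applies to the fragment *including its own tail*, which makes nested
decoding unambiguous. Recursion depth is capped at one per fragment and
fragments shorter than k go raw, so encoding always terminates. Reads
containing bytes outside {A,C,G,T,N} bypass the mapper entirely and are
stored raw, since the segment alphabet cannot carry them.

## Read stream dialect

The stream is newline-delimited text, one read per line: fragments in order
(`POS`, optional literal `0` palindrome flag, then segments concatenated as
`<len><type>` with I/S bases inlined, e.g. `4M2IAA4M1D2M`), then an optional
corrections token (`16A7C`). `0 <read>` stores a raw read. The grammar is
self-delimiting and parseable with one token of lookahead: position tokens
are pure integers, segment strings start with a digit but contain type
letters, raw fragments are pure ACGTN, and a corrections token mixes digits
and bases and is always last. Text rather than bit-packing is deliberate:
LZMA absorbs the residual redundancy, and the stream stays inspectable.

## Quality codec

Only runs of n > 2 are tokenized (a flagged character plus a length byte
storing n − 1, capping runs at 256; longer runs are split so no sub-minimal
remainder is left). Blocks of ≥ 4 runs strictly alternating between two
characters X…Y are rewritten as flagged X + length, the interior lengths
bare, flagged Y + length. Two choices here were open and are resolved as
follows:

* The length byte stores **n − 1**: the printed cap of 256 does not fit an
  8-bit byte otherwise.
* Interior runs of an alternation block are restricted to n ∈ [3, 33], so
  their bare bytes (2..32) are disjoint from both literal quality bytes
  (≥ 33) and flagged bytes (≥ 128). This makes the simplified form
  prefix-free with *no* extra framing byte — the example block still costs
  exactly 6 symbols — and blocks with longer interior runs simply pass
  through unsimplified, which only forgoes a saving.

Qualities of all records are concatenated before coding (runs may span
record boundaries) and split back by read length at decode time. Lossy
quality compression is out of scope by design.

## Archive format

Little-endian header: magic `RFQZ`, version, k (u8), L (u16), e (f64),
CRC-32 and length of the normalized reference, flags, record count; then
three length-prefixed LZMA payloads (metadata, reads, qualities). The
reference is not stored — that is the point of reference-based compression —
and the checksum guarantees a wrong or modified reference fails loudly
instead of decoding garbage. Archives are deterministic for fixed input and
parameters: no timestamps, fixed LZMA preset.

## Synthetic corpora

The generator emulates exactly the features the codecs exploit: reads
sampled uniformly from a random reference with configurable GC fraction,
i.i.d. substitutions and 1–2-base indels, an optional reverse-complement
fraction, a fraction of purely random (unmappable) reads, quality strings
built from geometric-length runs over a small alphabet with optional
two-character alternation, and 454-style (`RUN.n CODE length = n`) or
Illumina-style headers. Defaults — 100 kb reference, 10,000 reads of 100 bp,
1% substitutions, 0.1% indels, 5% reverse-complement, 1% unmappable — are
the standard study conditions used by the end-to-end tests; unit tests use
smaller explicit configurations so the whole suite runs in seconds on one
CPU. Every simulated read carries a truth record (position, strand, edit
script) that replays to the read itself.

What the generator does *not* model: platform-specific error profiles
(454 homopolymer miscalls, cycle-dependent Illumina quality decay), real
genome repeat structure, and paired-end structure. Passing tests therefore
demonstrate correctness (byte-exact losslessness under diverse inputs,
including adversarial ones) and mechanism-level accuracy (seed voting
recovers planted positions), not compression ratios on real instruments —
real-data ratios depend on header dialects and quality-score entropy that
the simulator only sketches.

The mapper-accuracy fixture samples error-free reads with at least one
indexed (CG-prefixed) k-mer, matching the scope of the claim it tests: a
read with no seed is unmappable by construction and is stored raw.

## Known limitations

* Seed restriction to `CG` makes mapping sensitivity depend on GC content;
  AT-rich references degrade toward raw storage (still lossless).
* The greedy aligner can wander a few bases past a true breakpoint when
  coincidental matches follow; the palindrome tail still anchors correctly
  and corrections absorb any slippage.
* Multi-line (wrapped) FASTQ, gzip input transparency and SAM/BAM are out of
  scope; the compressor is single-threaded.
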