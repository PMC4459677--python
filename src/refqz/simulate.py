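"""Synthetic FASTQ/reference generator with ground-truth sampling records.

The generator emulates the statistical structure the compressor exploits:
reads sampled from a reference with configurable substitution/indel rates and
an optional reverse-complement fraction, run-rich quality strings drawn from
a small alphabet with geometric run lengths and optional two-character
alternation, and either 454-style headers (shared identifier prefix, running
record number, redundant ``length = n`` token) or Illumina-style headers
(colon-separated coordinates).  Every read carries a truth record — sampling
position, strand and the exact edit script — that replays to the read itself,
so mapper accuracy tests never re-derive ground truth.

Everything is driven by one integer seed; the same seed yields a
byte-identical corpus.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np

from .fastq_io import FastqRecord, ReferenceSequence, write_fastq
from .mapper import reverse_complement

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic corpus.

    Defaults describe the standard corpus: a 100 kb random reference, 10,000
    reads of 100 bases with 1% substitutions and 0.1% indels, a small
    reverse-complement and unmappable fraction, and run-rich qualities.
    """

    ref_length: int = 100_000
    gc_fraction: float = 0.5
    n_reads: int = 10_000
    read_length: int = 100
    read_length_range: tuple[int, int] | None = None  # uniform variable lengths
    substitution_rate: float = 0.01
    indel_rate: float = 0.001
    revcomp_fraction: float = 0.05
    unmappable_fraction: float = 0.01
    require_seed: bool = False  # resample until the read contains a CG k-mer
    quality_alphabet: str = "#,:FJ"
    quality_run_mean: float = 5.0
    alternation_prob: float = 0.3
    header_style: str = "454"  # or "illumina"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "indel_rate",
            "revcomp_fraction",
            "unmappable_fraction",
            "gc_fraction",
            "alternation_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ref_length < 1:
            raise ValueError("ref_length must be >= 1")
        if self.header_style not in ("454", "illumina"):
            raise ValueError(f"unknown header style {self.header_style!r}")


@dataclass
class TruthRecord:
    """Ground truth for one simulated read.

    ``pos`` is the 1-based reference position of the sampled window (0 for
    random/unmappable reads), ``strand`` '+'/'-'/'*', ``window_len`` the number
    of reference bases consumed, and ``ops`` the edit script applied to the
    oriented window: a list of ("M", count) / ("S", base) / ("I", bases) /
    ("D", count) steps.
    """

    read_id: str
    pos: int
    strand: str
    window_len: int
    ops: list[tuple] = field(default_factory=list)

    def replay(self, ref: ReferenceSequence) -> str:
        """Reapply the edit script to the reference window; equals the read."""
        window = ref.seq[self.pos - 1 : self.pos - 1 + self.window_len]
        if self.strand == "-":
            window = reverse_complement(window)
        out: list[str] = []
        wi = 0
        for op in self.ops:
            kind = op[0]
            if kind == "M":
                out.append(window[wi : wi + op[1]])
                wi += op[1]
            elif kind == "S":
                out.append(op[1])
                wi += 1
            elif kind == "I":
                out.append(op[1])
            elif kind == "D":
                wi += op[1]
        return "".join(out)


def generate_reference(config: SimulationConfig) -> ReferenceSequence:
    """Random i.i.d. reference with the configured GC fraction."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(np.array(list(_BASES))[rng.choice(4, size=config.ref_length, p=probs)])
    return ReferenceSequence(name="synthetic_ref", seq=seq)


def _read_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.read_length_range is not None:
        lo, hi = config.read_length_range
        return int(rng.integers(lo, hi + 1))
    return config.read_length


def _has_seed_kmer(read: str, k: int = 10) -> bool:
    j = read.find("CG")
    while j != -1:
        if j + k <= len(read) and "N" not in read[j : j + k]:
            return True
        j = read.find("CG", j + 1)
    return False


def _sample_read(
    config: SimulationConfig, ref: ReferenceSequence, rng: np.random.Generator, rl: int
) -> tuple[str, int, str, int, list[tuple]]:
    """One edited read plus its truth fields (read, pos, strand, window_len, ops)."""
    margin = rl + 10 + int(3 * rl * config.indel_rate)
    start = int(rng.integers(0, max(1, len(ref.seq) - margin)))
    window = ref.seq[start : start + margin]
    strand = "-" if rng.random() < config.revcomp_fraction else "+"
    if strand == "-":
        window = reverse_complement(window)
    out: list[str] = []
    ops: list[tuple] = []
    wi = 0
    match_run = 0

    def flush() -> None:
        nonlocal match_run
        if match_run:
            ops.append(("M", match_run))
            match_run = 0

    while len(out) < rl and wi < len(window):
        r = rng.random()
        if r < config.substitution_rate:
            flush()
            old = window[wi]
            new = _BASES[int(rng.integers(0, 4))]
            while new == old:
                new = _BASES[int(rng.integers(0, 4))]
            out.append(new)
            ops.append(("S", new))
            wi += 1
        elif r < config.substitution_rate + config.indel_rate / 2:
            flush()
            ins = _BASES[int(rng.integers(0, 4))]
            out.append(ins)
            ops.append(("I", ins))
        elif r < config.substitution_rate + config.indel_rate:
            flush()
            ops.append(("D", 1))
            wi += 1
        else:
            out.append(window[wi])
            match_run += 1
            wi += 1
    flush()
    read = "".join(out)
    window_len = wi
    if strand == "-":
        # the consumed prefix of the oriented (reverse-complemented) window
        # corresponds to the suffix of the forward-strand window; re-anchor so
        # replay() extracts exactly the consumed reference bases
        pos = start + (len(window) - window_len) + 1
    else:
        pos = start + 1
    return read, pos, strand, window_len, ops


def _random_read(rng: np.random.Generator, rl: int) -> str:
    return "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=rl))


def _quality_string(config: SimulationConfig, rng: np.random.Generator, rl: int) -> str:
    alphabet = config.quality_alphabet
    out: list[str] = []
    prev: str | None = None
    prev2: str | None = None
    p = 1.0 / max(config.quality_run_mean, 1.000001)
    while len(out) < rl:
        if prev2 is not None and rng.random() < config.alternation_prob:
            c = prev2
        else:
            c = alphabet[int(rng.integers(0, len(alphabet)))]
        run = int(rng.geometric(p))
        out.extend(c * min(run, rl - len(out)))
        prev2, prev = prev, c
    return "".join(out)


_CODE_CHARS = string.ascii_uppercase + string.digits


def _headers(
    config: SimulationConfig, rng: np.random.Generator, read_lengths: list[int]
) -> list[str]:
    if config.header_style == "454":
        run_id = f"SRR{int(rng.integers(100000, 999999))}"
        shared = "".join(_CODE_CHARS[int(i)] for i in rng.integers(0, 36, size=9))
        out = []
        for i, rl in enumerate(read_lengths, start=1):
            code = shared + "".join(_CODE_CHARS[int(j)] for j in rng.integers(0, 36, size=5))
            out.append(f"@{run_id}.{i} {code} length = {rl}")
        return out
    out = []
    tile = int(rng.integers(1, 100))
    for _ in read_lengths:
        x = int(rng.integers(1000, 20000))
        y = int(rng.integers(1000, 20000))
        out.append(f"@SIM01:1:FC001:1:{tile}:{x}:{y} 1:N:0:ACGTAC")
    return out


def generate_fastq(
    config: SimulationConfig, ref: ReferenceSequence
) -> tuple[list[FastqRecord], list[TruthRecord]]:
    """Simulate a corpus against ``ref``; returns records plus truth table."""
    rng = np.random.default_rng(config.seed + 1)
    reads: list[str] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_reads):
        rl = _read_length(config, rng)
        if rng.random() < config.unmappable_fraction:
            reads.append(_random_read(rng, rl))
            truths.append(TruthRecord(read_id=str(i + 1), pos=0, strand="*", window_len=0))
            continue
        for _ in range(200):
            read, pos, strand, window_len, ops = _sample_read(config, ref, rng, rl)
            if not config.require_seed or (strand == "+" and _has_seed_kmer(read)):
                break
        else:
            raise RuntimeError("could not sample a seed-bearing read; check gc_fraction")
        reads.append(read)
        truths.append(TruthRecord(str(i + 1), pos, strand, window_len, ops))
    lengths = [len(r) for r in reads]
    headers = _headers(config, rng, lengths)
    records = [
        FastqRecord(h, r, "+", _quality_string(config, rng, len(r)))
        for h, r in zip(headers, reads)
    ]
    return records, truths


def corpus_bytes(config: SimulationConfig, ref: ReferenceSequence) -> bytes:
    """FASTQ bytes of a simulated corpus (LF terminators)."""
    records, _ = generate_fastq(config, ref)
    return write_fastq(records)


def reference_fasta(ref: ReferenceSequence, width: int = 70) -> bytes:
    """Serialize a reference as wrapped FASTA."""
    lines = [f">{ref.name}"]
    for i in range(0, len(ref.seq), width):
        lines.append(ref.seq[i : i + width])
    return ("\n".join(lines) + "\n").encode("ascii")


def truth_tsv(truths: list[TruthRecord]) -> str:
    """Sidecar tab-separated truth table (one row per read)."""
    rows = ["read_id\tpos\tstrand\twindow_len\tops"]
    for t in truths:
        ops = ";".join(f"{kind}{val}" for kind, val in t.ops)
        rows.append(f"{t.read_id}\t{t.pos}\t{t.strand}\t{t.window_len}\t{ops}")
    return "\n".join(rows) + "\n"


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: same conditions, different seed."""
    return replace(config, seed=seed)
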