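"""FASTQ / FASTA byte-level I/O.

FASTQ parsing is deliberately byte-faithful: record text is kept exactly as
read (minus line terminators), and the terminator layout (global style plus a
per-line exception list) is recorded so that serialization reproduces the
original byte stream exactly, including a missing final newline or mixed
LF/CRLF files.  The reference FASTA is read through Bio.SeqIO and normalized
to the {A,C,G,T,N} alphabet.
"""

from __future__ import annotations

import io
import logging
import warnings
import zlib
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import FastaFormatError, FastqFormatError

logger = logging.getLogger(__name__)

# terminator codes used in LineLayout.exceptions and the archive
TERM_LF = 0
TERM_CRLF = 1
TERM_NONE = 2  # only legal on the final line

_TERM_BYTES = {TERM_LF: "\n", TERM_CRLF: "\r\n", TERM_NONE: ""}

_IUPAC_TO_N = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVUrsywkmbdhvu"}
)


@dataclass
class FastqRecord:
    """One four-line FASTQ record, byte-exact (terminators stripped)."""

    header: str
    read: str
    plus_line: str
    quality: str

    def validate(self, index: int) -> None:
        if not self.header.startswith("@"):
            raise FastqFormatError(f"record {index}: header does not start with '@'")
        if not self.plus_line.startswith("+"):
            raise FastqFormatError(f"record {index}: third line does not start with '+'")
        if len(self.quality) != len(self.read):
            raise FastqFormatError(
                f"record {index}: quality length {len(self.quality)} != read length {len(self.read)}"
            )


@dataclass
class ReferenceSequence:
    """Normalized reference: uppercase {A,C,G,T,N} concatenation of all records."""

    name: str
    seq: str

    @property
    def checksum(self) -> int:
        """CRC-32 of the normalized sequence bytes (guards decompression)."""
        return zlib.crc32(self.seq.encode("ascii"))


@dataclass
class LineLayout:
    """Global line-terminator style plus per-line exceptions.

    ``exceptions`` maps a 0-based line index to a terminator code that differs
    from ``style``; a ``TERM_NONE`` entry on the last line records a file with
    no trailing newline.
    """

    style: int = TERM_LF
    exceptions: dict[int, int] = field(default_factory=dict)

    def terminator(self, line_index: int) -> str:
        return _TERM_BYTES[self.exceptions.get(line_index, self.style)]


def _split_lines(text: str) -> tuple[list[str], list[int]]:
    """Split into (contents, terminator codes), preserving terminator info."""
    contents: list[str] = []
    terms: list[int] = []
    start = 0
    n = len(text)
    while start < n:
        nl = text.find("\n", start)
        if nl == -1:
            contents.append(text[start:])
            terms.append(TERM_NONE)
            break
        if nl > start and text[nl - 1] == "\r":
            contents.append(text[start : nl - 1])
            terms.append(TERM_CRLF)
        else:
            contents.append(text[start:nl])
            terms.append(TERM_LF)
        start = nl + 1
    return contents, terms


def parse_fastq(data: bytes) -> tuple[list[FastqRecord], LineLayout]:
    """Parse a FASTQ byte stream into records plus its terminator layout.

    Raises :class:`FastqFormatError` on a truncated record (line count not a
    multiple of four) or a read/quality length mismatch, naming the record.
    """
    if not data:
        return [], LineLayout()
    text = data.decode("latin-1")
    lines, terms = _split_lines(text)
    if len(lines) % 4 != 0:
        raise FastqFormatError(
            f"truncated FASTQ: {len(lines)} lines is not a multiple of 4 "
            f"(record {len(lines) // 4} is incomplete)"
        )
    style = terms[0]
    layout = LineLayout(style=style)
    for i, t in enumerate(terms):
        if t != style:
            layout.exceptions[i] = t
    records = []
    for r in range(0, len(lines), 4):
        rec = FastqRecord(lines[r], lines[r + 1], lines[r + 2], lines[r + 3])
        rec.validate(r // 4)
        records.append(rec)
    return records, layout


def write_fastq(records: list[FastqRecord], layout: LineLayout | None = None) -> bytes:
    """Serialize records back to bytes; exact inverse of :func:`parse_fastq`."""
    if layout is None:
        layout = LineLayout()
    out = io.StringIO()
    i = 0
    for rec in records:
        for line in (rec.header, rec.read, rec.plus_line, rec.quality):
            out.write(line)
            out.write(layout.terminator(i))
            i += 1
    return out.getvalue().encode("latin-1")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map every non-ACGT base (IUPAC ambiguity codes etc.) to N."""
    s = seq.upper().translate(_IUPAC_TO_N)
    if set(s) - set("ACGTN"):
        s = "".join(c if c in "ACGTN" else "N" for c in s)
    return s


def parse_fasta(data: bytes) -> ReferenceSequence:
    """Load a FASTA byte stream as one normalized reference.

    Multiple records are concatenated in file order; the name of the first
    record is kept.  Empty input is a hard error; content that is not
    predominantly nucleotide raises a warning (it would map almost nothing).
    """
    handle = io.StringIO(data.decode("latin-1"))
    names: list[str] = []
    parts: list[str] = []
    for rec in SeqIO.parse(handle, "fasta"):
        names.append(rec.id)
        parts.append(str(rec.seq))
    if not parts or not any(parts):
        raise FastaFormatError("empty or record-less FASTA reference")
    raw = "".join(parts)
    seq = normalize_sequence(raw)
    n_frac = seq.count("N") / len(seq)
    if n_frac > 0.5:
        warnings.warn(
            f"reference is only {100 * (1 - n_frac):.0f}% A/C/G/T after "
            "normalization; mapping will be ineffective",
            stacklevel=2,
        )
    logger.debug("loaded reference %s: %d bases (%d records)", names[0], len(seq), len(names))
    return ReferenceSequence(name=names[0], seq=seq)


def split_streams(
    records: list[FastqRecord],
) -> tuple[list[str], list[str], list[str], list[str] | None]:
    """Split records into parallel header/read/quality streams.

    Returns ``(headers, reads, qualities, plus_lines)`` where ``plus_lines``
    is ``None`` when every separator line is a bare ``"+"`` (the common case,
    recorded as a single flag in the archive) and the verbatim lines otherwise.
    """
    headers = [r.header for r in records]
    reads = [r.read for r in records]
    quals = [r.quality for r in records]
    if all(r.plus_line == "+" for r in records):
        return headers, reads, quals, None
    return headers, reads, quals, [r.plus_line for r in records]


def interleave_streams(
    headers: list[str],
    reads: list[str],
    qualities: list[str],
    plus_lines: list[str] | None,
) -> list[FastqRecord]:
    """Inverse of :func:`split_streams`."""
    if not (len(headers) == len(reads) == len(qualities)):
        raise FastqFormatError("stream lengths disagree")
    if plus_lines is None:
        plus_lines = ["+"] * len(headers)
    return [
        FastqRecord(h, r, p, q)
        for h, r, p, q in zip(headers, reads, plus_lines, qualities)
    ]
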