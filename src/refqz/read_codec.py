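"""Serialization of read mappings to the compact text read stream.

One line per read.  A line is a chain of fragments followed by an optional
corrections token:

``POS [0] SEGMENTS``
    a mapped fragment: 1-based reference position, an optional literal ``0``
    palindrome flag, then the segment string — per-segment ``<len><type>``
    concatenated without separators, with the read bases of I/S segments
    inlined right after their type letter (``4M2IAA4M1D2M``).
``0 RAW``
    an unmapped fragment stored verbatim.  When it is the *first* fragment
    the rest of the line is the raw read (which may then contain any byte
    except a newline); nested raw fragments are always over {A,C,G,T,N}.
``16A7C``
    corrections token (delta-coded positions, each followed by the true
    base); always last on the line.

The stream is self-delimiting (one record per newline-separated line) and the
decoder — not the metadata stream — is the authority for read lengths.
"""

from __future__ import annotations

import re

from .errors import CorruptArchiveError
from .fastq_io import ReferenceSequence
from .mapper import AlignmentSegment, ReadMapping, apply_corrections, reconstruct

_SEG_RE = re.compile(r"([0-9]+)([MIDS])")
_RAW_RE = re.compile(r"^[ACGTN]+$")
_CORR_RE = re.compile(r"([0-9]+)([ACGTN])")
_INT_RE = re.compile(r"^[0-9]+$")


def _segment_string(segments: list[AlignmentSegment]) -> str:
    parts = []
    for seg in segments:
        parts.append(f"{seg.mlength}{seg.mtype}")
        if seg.mtype in ("I", "S"):
            parts.append(seg.mis_values)
    return "".join(parts)


def encode_mapping(mapping: ReadMapping) -> str:
    """Serialize one (verified) mapping to its stream line."""
    tokens: list[str] = []
    frag: ReadMapping | None = mapping
    first = True
    while frag is not None:
        if frag.pos == 0:
            if first:
                return "0 " + (frag.raw or "")
            tokens.append("0")
            if frag.raw:
                tokens.append(frag.raw)
        else:
            tokens.append(str(frag.pos))
            if frag.pal:
                tokens.append("0")
            tokens.append(_segment_string(frag.segments))
        frag = frag.tail
        first = False
    if mapping.corrections:
        tokens.append("".join(f"{d}{b}" for d, b in mapping.corrections))
    return " ".join(tokens)


def _parse_segments(s: str, where: str) -> list[AlignmentSegment]:
    segments: list[AlignmentSegment] = []
    j = 0
    while j < len(s):
        m = _SEG_RE.match(s, j)
        if m is None:
            raise CorruptArchiveError(f"{where}: bad segment string {s!r}")
        length = int(m.group(1))
        mtype = m.group(2)
        if length < 1:
            raise CorruptArchiveError(f"{where}: zero-length segment in {s!r}")
        j = m.end()
        values = ""
        if mtype in ("I", "S"):
            values = s[j : j + length]
            if len(values) != length or not _RAW_RE.match(values):
                raise CorruptArchiveError(f"{where}: truncated mismatch values in {s!r}")
            j += length
        segments.append(AlignmentSegment(length, mtype, values))
    if not segments:
        raise CorruptArchiveError(f"{where}: empty segment string")
    return segments


def parse_line(line: str, where: str = "read") -> ReadMapping:
    """Parse one stream line back into a :class:`ReadMapping` chain."""
    if line.startswith("0 ") or line == "0":
        return ReadMapping(pos=0, raw=line[2:])
    tokens = line.split(" ")
    i = 0
    fragments: list[ReadMapping] = []
    corrections: list[tuple[int, str]] = []
    while i < len(tokens):
        t = tokens[i]
        if _INT_RE.match(t):
            pos = int(t)
            i += 1
            if pos == 0:
                raw = ""
                if i < len(tokens) and _RAW_RE.match(tokens[i]):
                    raw = tokens[i]
                    i += 1
                fragments.append(ReadMapping(pos=0, raw=raw))
            else:
                pal = False
                if (
                    i + 1 < len(tokens)
                    and tokens[i] == "0"
                    and _SEG_RE.match(tokens[i + 1])
                ):
                    pal = True
                    i += 1
                if i >= len(tokens):
                    raise CorruptArchiveError(f"{where}: fragment at {pos} has no segments")
                segments = _parse_segments(tokens[i], where)
                i += 1
                fragments.append(ReadMapping(pos=pos, pal=pal, segments=segments))
        else:
            # corrections token: must be last
            if i != len(tokens) - 1 or not t:
                raise CorruptArchiveError(f"{where}: unexpected token {t!r}")
            j = 0
            prev_end = 0
            for m in _CORR_RE.finditer(t):
                if m.start() != prev_end:
                    raise CorruptArchiveError(f"{where}: bad corrections token {t!r}")
                corrections.append((int(m.group(1)), m.group(2)))
                prev_end = m.end()
                j = m.end()
            if j != len(t) or not corrections:
                raise CorruptArchiveError(f"{where}: bad corrections token {t!r}")
            i += 1
    if not fragments:
        raise CorruptArchiveError(f"{where}: empty record line")
    # rebuild the fragment chain
    for a, b in zip(fragments, fragments[1:]):
        a.tail = b
    fragments[0].corrections = corrections
    return fragments[0]


def decode_read(line: str, ref: ReferenceSequence, where: str = "read") -> str:
    """Decode one stream line to the original read string."""
    mapping = parse_line(line, where)
    return apply_corrections(reconstruct(mapping, ref), mapping.corrections)


def encode_stream(mappings: list[ReadMapping]) -> str:
    """Newline-joined stream of all read lines."""
    return "\n".join(encode_mapping(m) for m in mappings)


def decode_stream(text: str, ref: ReferenceSequence, n_records: int) -> list[str]:
    """Decode the whole read stream back to the list of reads."""
    if n_records == 0:
        if text:
            raise CorruptArchiveError("read stream should be empty")
        return []
    lines = text.split("\n")
    if len(lines) != n_records:
        raise CorruptArchiveError(
            f"read stream has {len(lines)} records, expected {n_records}"
        )
    return [decode_read(ln, ref, where=f"read {i}") for i, ln in enumerate(lines)]
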