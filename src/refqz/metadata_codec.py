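"""Incremental encoding of the FASTQ header (metadata) stream.

Sequencer headers are highly repetitive: a run identifier with a running
record number, an informative per-read field, and often a redundant
``length = <n>`` token.  The codec stores the first header plainly and every
later one as a small diff against its immediate predecessor.

Each record is coded in one of four modes:

``A``
    first token matches ``<template><ordinal>`` and the header ends in
    ``length = <read length>``; only ``(prefix_len, suffix)`` of the
    informative field versus the previous record's field is stored.
``B``
    template matches but there is no (or a non-matching) length token;
    the field after the first token is diff-coded the same way.
``D``
    whole-line prefix diff against the previous header (fallback for headers
    that do not fit the template, e.g. Illumina colon-separated ids whose
    coordinates change per record).
``V``
    verbatim line (first record, or pathological input).

Decoding is byte-exact: the decoder reconstructs each header and then updates
its "previous field" state with the *same* extraction function the encoder
used, so both sides stay in lockstep by construction.  Read lengths are not
stored; the read-stream decoder supplies them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import CorruptArchiveError

_TRAILING_INT_RE = re.compile(r"^(.*?)([0-9]+)$")


def common_prefix_len(a: str, b: str) -> int:
    """Length of the longest common prefix of two strings."""
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


@dataclass
class MetadataCode:
    """Encoded header stream: an id template plus one coded entry per record.

    Entries are ``("V", line)`` or ``(mode, prefix_len, variance)`` with mode
    in {A, B, D}.
    """

    template: str | None
    records: list[tuple] = field(default_factory=list)


def _derive_template(first_header: str) -> str | None:
    """Template = first token minus its trailing number, if that number is 1."""
    if not first_header.startswith("@"):
        return None
    token0 = first_header[1:].split(" ", 1)[0]
    m = _TRAILING_INT_RE.match(token0)
    if m and m.group(2) == str(1):
        return m.group(1)
    return None


def _extract_field(
    header: str, ordinal: int, read_length: int, template: str | None
) -> tuple[str | None, bool]:
    """Informative field of a template-conforming header, plus length-token flag.

    Returns ``(None, False)`` when the header does not fit the template
    (wrong leading token, tabs, doubled spaces), in which case the record
    falls back to whole-line diff coding.
    """
    if template is None or not header.startswith("@") or "\t" in header:
        return None, False
    tokens = header[1:].split(" ")
    if "" in tokens or tokens[0] != f"{template}{ordinal}":
        return None, False
    rest = tokens[1:]
    if len(rest) >= 3 and rest[-3:] == ["length", "=", str(read_length)]:
        return " ".join(rest[:-3]), True
    if not rest:
        return None, False
    return " ".join(rest), False


def _rebuild_header(
    mode: str, fld: str, ordinal: int, read_length: int, template: str
) -> str:
    parts = [f"{template}{ordinal}"]
    if fld:
        parts.append(fld)
    if mode == "A":
        parts.extend(["length", "=", str(read_length)])
    return "@" + " ".join(parts)


def encode_metadata(headers: list[str], read_lengths: list[int]) -> MetadataCode:
    """Encode a header list against the parallel read lengths."""
    if not headers:
        return MetadataCode(template=None)
    if len(headers) != len(read_lengths):
        raise ValueError("headers and read_lengths must be parallel")
    template = _derive_template(headers[0])
    code = MetadataCode(template=template, records=[("V", headers[0])])
    prev_line = headers[0]
    prev_field, _ = _extract_field(headers[0], 1, read_lengths[0], template)
    for i in range(1, len(headers)):
        h = headers[i]
        fld, len_ok = _extract_field(h, i + 1, read_lengths[i], template)
        if fld is not None and prev_field is not None:
            p = common_prefix_len(prev_field, fld)
            code.records.append(("A" if len_ok else "B", p, fld[p:]))
        else:
            p = common_prefix_len(prev_line, h)
            code.records.append(("D", p, h[p:]))
        prev_line = h
        prev_field = fld
    return code


def decode_metadata(code: MetadataCode, read_lengths: list[int]) -> list[str]:
    """Exact inverse of :func:`encode_metadata` (read lengths must match)."""
    if not code.records:
        return []
    if len(code.records) != len(read_lengths):
        raise CorruptArchiveError("metadata record count disagrees with read stream")
    first = code.records[0]
    if first[0] != "V":
        raise CorruptArchiveError("metadata stream does not start with a plain record")
    headers = [first[1]]
    template = code.template
    prev_line = headers[0]
    prev_field, _ = _extract_field(headers[0], 1, read_lengths[0], template)
    for i in range(1, len(code.records)):
        entry = code.records[i]
        mode = entry[0]
        if mode == "V":
            h = entry[1]
        else:
            _, p, variance = entry
            if mode in ("A", "B"):
                if prev_field is None or p > len(prev_field):
                    raise CorruptArchiveError(
                        f"metadata record {i}: prefix length {p} exceeds previous field"
                    )
                fld = prev_field[:p] + variance
                if template is None:
                    raise CorruptArchiveError("template record without a template")
                h = _rebuild_header(mode, fld, i + 1, read_lengths[i], template)
            elif mode == "D":
                if p > len(prev_line):
                    raise CorruptArchiveError(
                        f"metadata record {i}: prefix length {p} exceeds previous line"
                    )
                h = prev_line[:p] + variance
            else:
                raise CorruptArchiveError(f"metadata record {i}: unknown mode {mode!r}")
        headers.append(h)
        prev_line = h
        prev_field, _ = _extract_field(h, i + 1, read_lengths[i], template)
    return headers


def serialize_code(code: MetadataCode) -> str:
    """Text form stored in the archive: template line, then one line per record."""
    lines = ["T1 " + code.template if code.template is not None else "T0"]
    for entry in code.records:
        if entry[0] == "V":
            lines.append("V " + entry[1])
        else:
            mode, p, variance = entry
            lines.append(f"{mode} {p} {variance}")
    return "\n".join(lines)


def parse_code(text: str, n_records: int) -> MetadataCode:
    """Inverse of :func:`serialize_code`."""
    lines = text.split("\n")
    if len(lines) != n_records + 1:
        raise CorruptArchiveError(
            f"metadata block has {len(lines) - 1} records, expected {n_records}"
        )
    tline = lines[0]
    if tline.startswith("T1 "):
        template: str | None = tline[3:]
    elif tline == "T0":
        template = None
    else:
        raise CorruptArchiveError("bad metadata template line")
    records: list[tuple] = []
    for ln in lines[1:]:
        if ln.startswith("V "):
            records.append(("V", ln[2:]))
        else:
            parts = ln.split(" ", 2)
            if len(parts) != 3 or parts[0] not in ("A", "B", "D"):
                raise CorruptArchiveError(f"bad metadata record line {ln!r}")
            try:
                p = int(parts[1])
            except ValueError as exc:
                raise CorruptArchiveError(f"bad prefix length in {ln!r}") from exc
            records.append((parts[0], p, parts[2]))
    return MetadataCode(template=template, records=records)
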