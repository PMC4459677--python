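"""Archive format and compress/decompress orchestration.

An archive holds a fixed binary header (magic, version, mapping parameters,
reference CRC-32 and length, record count) followed by three length-prefixed
LZMA-compressed payloads in order: metadata, reads, qualities.  The reference
itself is *not* stored — decompression requires the same reference, and the
checksum turns a wrong-reference mistake into a clean error instead of silent
corruption.

The metadata payload carries, as text: the line-terminator layout, the
incremental header code block, and (only when some separator line is not a
bare ``+``) the verbatim plus lines.  Qualities of all records are
concatenated before RLL coding (runs may span record boundaries) and split
back using the read lengths recovered from the read stream.
"""

from __future__ import annotations

import logging
import lzma
import struct
from dataclasses import dataclass
from pathlib import Path

from . import fastq_io, metadata_codec, read_codec
from .errors import CorruptArchiveError, RefqzError, ReferenceMismatchError
from .fastq_io import LineLayout, ReferenceSequence
from .kmer_index import MappingParams, build_index
from .mapper import map_read, verify_and_correct
from .quality_codec import rll_decode, rll_encode

logger = logging.getLogger(__name__)

MAGIC = b"RFQZ"
VERSION = 1
_HEADER = struct.Struct("<4sBBHdIQBQ")  # magic, ver, k, L, e, crc, reflen, flags, nrec
_FLAG_PLUS_VERBATIM = 0x01
_LZMA_PRESET = 6  # fixed for reproducibility

_READ_ALPHABET = frozenset("ACGTN")


@dataclass
class ArchiveStats:
    """Per-stream sizes collected while compressing (bytes)."""

    original_size: int
    archive_size: int
    metadata_raw: int
    metadata_packed: int
    reads_raw: int
    reads_packed: int
    qualities_raw: int
    qualities_packed: int
    n_records: int
    n_mapped: int
    n_unmapped: int

    @property
    def ratio(self) -> float:
        return compression_ratio(self.original_size, self.archive_size)


def compression_ratio(original_size: int, compressed_size: int) -> float:
    """Compressed size divided by original size (smaller is better)."""
    if original_size <= 0:
        raise RefqzError("original size must be positive")
    return compressed_size / original_size


def _pack_layout(layout: LineLayout) -> str:
    items = sorted(layout.exceptions.items())
    head = f"TERM {layout.style} {len(items)}"
    return "\n".join([head, *(f"{idx} {code}" for idx, code in items)])


def _encode_metadata_payload(
    headers: list[str],
    read_lengths: list[int],
    layout: LineLayout,
    plus_lines: list[str] | None,
) -> bytes:
    parts = [_pack_layout(layout)]
    parts.append(metadata_codec.serialize_code(metadata_codec.encode_metadata(headers, read_lengths)))
    if plus_lines is not None:
        parts.append("\n".join(plus_lines))
    return "\n".join(parts).encode("latin-1")


def _decode_metadata_payload(
    payload: bytes, n_records: int, read_lengths: list[int], plus_verbatim: bool
) -> tuple[list[str], LineLayout, list[str] | None]:
    lines = payload.decode("latin-1").split("\n")
    pos = 0
    head = lines[pos].split(" ")
    if len(head) != 3 or head[0] != "TERM":
        raise CorruptArchiveError("bad terminator layout header")
    layout = LineLayout(style=int(head[1]))
    n_exc = int(head[2])
    pos += 1
    for _ in range(n_exc):
        idx, code = lines[pos].split(" ")
        layout.exceptions[int(idx)] = int(code)
        pos += 1
    meta_lines = n_records + 1 if n_records else 1
    code = metadata_codec.parse_code("\n".join(lines[pos : pos + meta_lines]), n_records)
    pos += meta_lines
    headers = metadata_codec.decode_metadata(code, read_lengths)
    plus: list[str] | None = None
    if plus_verbatim:
        plus = lines[pos : pos + n_records]
        if len(plus) != n_records:
            raise CorruptArchiveError("truncated plus-line block")
        pos += n_records
    if pos != len(lines):
        raise CorruptArchiveError("trailing bytes in metadata payload")
    return headers, layout, plus


def compress_bytes(
    data: bytes, ref: ReferenceSequence, params: MappingParams | None = None
) -> tuple[bytes, ArchiveStats]:
    """Compress a FASTQ byte stream against a normalized reference."""
    params = params or MappingParams()
    records, layout = fastq_io.parse_fastq(data)
    headers, reads, qualities, plus_lines = fastq_io.split_streams(records)
    index = build_index(ref, params)

    mappings = []
    n_unmapped = 0
    for read in reads:
        if set(read) <= _READ_ALPHABET:
            mapping = verify_and_correct(read, map_read(read, ref, index, params), ref)
        else:
            # bytes outside the mapping alphabet: store the read verbatim
            mapping = read_codec.ReadMapping(pos=0, raw=read)
        if mapping.pos == 0:
            n_unmapped += 1
        mappings.append(mapping)
    logger.info(
        "mapped %d/%d reads (%d unmapped)",
        len(reads) - n_unmapped,
        len(reads),
        n_unmapped,
    )

    meta_payload = _encode_metadata_payload(
        headers, [len(r) for r in reads], layout, plus_lines
    )
    reads_payload = read_codec.encode_stream(mappings).encode("latin-1")
    qual_payload = rll_encode("".join(qualities))

    packed = [lzma.compress(p, preset=_LZMA_PRESET) for p in (meta_payload, reads_payload, qual_payload)]
    flags = _FLAG_PLUS_VERBATIM if plus_lines is not None else 0
    header = _HEADER.pack(
        MAGIC,
        VERSION,
        params.k,
        params.L,
        params.e,
        ref.checksum,
        len(ref.seq),
        flags,
        len(records),
    )
    blob = bytearray(header)
    for p in packed:
        blob += struct.pack("<Q", len(p))
        blob += p
    stats = ArchiveStats(
        original_size=len(data),
        archive_size=len(blob),
        metadata_raw=len(meta_payload),
        metadata_packed=len(packed[0]),
        reads_raw=len(reads_payload),
        reads_packed=len(packed[1]),
        qualities_raw=len(qual_payload),
        qualities_packed=len(packed[2]),
        n_records=len(records),
        n_mapped=len(reads) - n_unmapped,
        n_unmapped=n_unmapped,
    )
    return bytes(blob), stats


def read_archive_header(blob: bytes) -> tuple[MappingParams, int, int, int, int, list[bytes]]:
    """Split an archive into (params, crc, reflen, flags, nrec, payloads)."""
    if len(blob) < _HEADER.size:
        raise CorruptArchiveError("archive shorter than its header")
    magic, version, k, L, e, crc, reflen, flags, nrec = _HEADER.unpack_from(blob, 0)
    if magic != MAGIC:
        raise CorruptArchiveError("not a refqz archive (bad magic)")
    if version != VERSION:
        raise CorruptArchiveError(f"unsupported archive version {version}")
    params = MappingParams(k=k, L=L, e=e)
    off = _HEADER.size
    payloads = []
    for _ in range(3):
        if off + 8 > len(blob):
            raise CorruptArchiveError("truncated payload length")
        (plen,) = struct.unpack_from("<Q", blob, off)
        off += 8
        if off + plen > len(blob):
            raise CorruptArchiveError("truncated payload")
        payloads.append(blob[off : off + plen])
        off += plen
    if off != len(blob):
        raise CorruptArchiveError("trailing bytes after payloads")
    return params, crc, reflen, flags, nrec, payloads


def decompress_bytes(blob: bytes, ref: ReferenceSequence) -> bytes:
    """Decompress an archive back to the byte-identical FASTQ stream."""
    _, crc, reflen, flags, nrec, payloads = read_archive_header(blob)
    if len(ref.seq) != reflen or ref.checksum != crc:
        raise ReferenceMismatchError(
            "reference does not match the one used at compression "
            f"(length {len(ref.seq)} vs {reflen}, checksum mismatch={ref.checksum != crc})"
        )
    meta_payload, reads_payload, qual_payload = (lzma.decompress(p) for p in payloads)
    reads = read_codec.decode_stream(reads_payload.decode("latin-1"), ref, nrec)
    lengths = [len(r) for r in reads]
    headers, layout, plus_lines = _decode_metadata_payload(
        meta_payload, nrec, lengths, bool(flags & _FLAG_PLUS_VERBATIM)
    )
    qual_concat = rll_decode(qual_payload)
    if len(qual_concat) != sum(lengths):
        raise CorruptArchiveError("quality stream length disagrees with reads")
    qualities = []
    off = 0
    for n in lengths:
        qualities.append(qual_concat[off : off + n])
        off += n
    records = fastq_io.interleave_streams(headers, reads, qualities, plus_lines)
    return fastq_io.write_fastq(records, layout)


def compress_file(
    fastq_path: str | Path,
    reference_path: str | Path,
    out_path: str | Path,
    params: MappingParams | None = None,
) -> ArchiveStats:
    """Compress ``fastq_path`` against ``reference_path`` into ``out_path``."""
    data = Path(fastq_path).read_bytes()
    ref = fastq_io.parse_fasta(Path(reference_path).read_bytes())
    blob, stats = compress_bytes(data, ref, params)
    Path(out_path).write_bytes(blob)
    return stats


def decompress_file(
    archive_path: str | Path,
    reference_path: str | Path,
    out_path: str | Path,
) -> int:
    """Decompress ``archive_path`` with ``reference_path``; returns bytes written."""
    blob = Path(archive_path).read_bytes()
    ref = fastq_io.parse_fasta(Path(reference_path).read_bytes())
    data = decompress_bytes(blob, ref)
    Path(out_path).write_bytes(data)
    return len(data)
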