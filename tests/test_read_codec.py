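"""Read-stream grammar: serialization and exact decoding."""

import pytest

from refqz.errors import CorruptArchiveError
from refqz.fastq_io import ReferenceSequence
from refqz.mapper import AlignmentSegment, ReadMapping, apply_corrections, reconstruct
from refqz.read_codec import decode_read, decode_stream, encode_mapping, encode_stream, parse_line


def test_exact_match_line(tiny_ref):
    m = ReadMapping(pos=1, segments=[AlignmentSegment(10, "M")])
    assert encode_mapping(m) == "1 10M"
    assert decode_read("1 10M", tiny_ref) == tiny_ref.seq[:10]


def test_raw_line(tiny_ref):
    m = ReadMapping(pos=0, raw="ACGNT")
    assert encode_mapping(m) == "0 ACGNT"
    assert decode_read("0 ACGNT", tiny_ref) == "ACGNT"


def test_empty_raw_read(tiny_ref):
    assert decode_read(encode_mapping(ReadMapping(pos=0, raw="")), tiny_ref) == ""


def test_deletion_with_corrections_line(tiny_ref):
    """'12 7M2D5M 16A7C' — segments plus the delta-correction example."""
    m = ReadMapping(
        pos=12,
        segments=[AlignmentSegment(7, "M"), AlignmentSegment(2, "D"), AlignmentSegment(5, "M")],
    )
    ref = ReferenceSequence("r", "A" * 40)
    base = reconstruct(m, ref)
    assert len(base) == 12
    # force residual differences at positions (clipped to the 12-base read)
    m.corrections = [(4, "C"), (7, "G")]
    line = encode_mapping(m)
    assert line == "12 7M2D5M 4C7G"
    assert decode_read(line, ref) == apply_corrections(base, m.corrections)


def test_palindrome_flag_round_trip(tiny_ref):
    head = ReadMapping(pos=8, segments=[AlignmentSegment(7, "M")])
    head.tail = ReadMapping(pos=15, pal=True, segments=[AlignmentSegment(8, "M")])
    line = encode_mapping(head)
    assert line == "8 7M 15 0 8M"
    parsed = parse_line(line)
    assert parsed.pos == 8 and parsed.tail.pal and parsed.tail.pos == 15
    assert decode_read(line, tiny_ref) == reconstruct(head, tiny_ref)


def test_insertion_values_inline(tiny_ref):
    m = ReadMapping(
        pos=6,
        segments=[
            AlignmentSegment(4, "M"),
            AlignmentSegment(2, "I", "AA"),
            AlignmentSegment(4, "M"),
            AlignmentSegment(1, "D"),
            AlignmentSegment(2, "M"),
        ],
    )
    line = encode_mapping(m)
    assert line == "6 4M2IAA4M1D2M"
    assert parse_line(line).segments == m.segments


def random_mapping(rng, ref, with_corrections=True):
    """Construct a random (but structurally valid) fragment chain."""
    n_frag = int(rng.integers(1, 4))
    frags = []
    for fi in range(n_frag):
        if fi > 0 and rng.random() < 0.3:
            raw = "".join("ACGTN"[int(b)] for b in rng.integers(0, 5, size=rng.integers(1, 20)))
            frags.append(ReadMapping(pos=0, raw=raw))
            continue
        pos = int(rng.integers(1, len(ref.seq) - 60))
        segments = []
        prev = None
        for _ in range(int(rng.integers(1, 5))):
            mtype = str(rng.choice([t for t in "MIDS" if t != prev]))
            prev = mtype
            ln = int(rng.integers(1, 8))
            vals = ""
            if mtype in "IS":
                vals = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=ln))
            segments.append(AlignmentSegment(ln, mtype, vals))
        if segments[-1].mtype == "D":  # keep the fragment read-producing
            segments.append(AlignmentSegment(3, "M"))
        frags.append(ReadMapping(pos=pos, pal=bool(rng.random() < 0.3), segments=segments))
    if frags[0].pos == 0:
        frags[0].pal = False
    for a, b in zip(frags, frags[1:]):
        a.tail = b
    top = frags[0]
    read = reconstruct(top, ref)
    if with_corrections and read and rng.random() < 0.5:
        n_corr = int(rng.integers(1, min(4, len(read) + 1)))
        positions = sorted(rng.choice(len(read), size=min(n_corr, len(read)), replace=False))
        prev_p = 0
        corrections = []
        for p in positions:
            corrections.append((int(p) + 1 - prev_p, "ACGTN"[int(rng.integers(0, 5))]))
            prev_p = int(p) + 1
        top.corrections = corrections
        read = apply_corrections(read, corrections)
    return top, read


def test_random_mappings_round_trip(small_ref, rng):
    for _ in range(500):
        mapping, read = random_mapping(rng, small_ref)
        line = encode_mapping(mapping)
        assert decode_read(line, small_ref) == read


def test_stream_is_self_delimiting(small_ref, rng):
    mappings, reads = zip(*(random_mapping(rng, small_ref) for _ in range(50)))
    text = encode_stream(list(mappings))
    assert decode_stream(text, small_ref, 50) == list(reads)


@pytest.mark.parametrize(
    "line",
    [
        "abc",  # no fragment
        "5",  # mapped fragment without segments
        "5 3X",  # unknown segment type
        "5 3IAB",  # truncated mismatch values
        "5 0M",  # zero-length segment
        "1 10M 7",  # malformed corrections token
        "999999 10M",  # reference overrun
    ],
)
def test_malformed_lines_raise(line, tiny_ref):
    with pytest.raises(CorruptArchiveError):
        decode_read(line, tiny_ref)
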