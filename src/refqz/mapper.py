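"""Light-weight seed-and-vote read mapping.

Mapping a read proceeds in three stages:

1. *Voting*: every CG-prefixed, N-free k-mer of the read that occurs in the
   reference index votes for the candidate start position
   ``ref_position - read_offset``; the candidate with the most votes is the
   putative mapping position.
2. *Greedy local alignment* from that position, base by base.  On a mismatch
   the three events substitution / deletion / insertion are probed and the
   one whose following few bases re-synchronize best is taken.  Extension
   stops when the running mismatch fraction would exceed ``e``.
3. *Fallbacks*: a read with no usable seed is stored raw (POS = 0).  When the
   alignment covers only a prefix of the read, the reverse complement of the
   remainder is sent through the mapper once more (the "palindrome" re-entry,
   flagged PAL) and attached as a tail fragment; a remainder that still fails
   is stored raw.

The emitted :class:`ReadMapping` is verified by reconstruction against the
original read; any residual difference is recorded as a delta-coded
correction, so decoding is byte-exact no matter how approximate the
alignment was.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import CorruptArchiveError, RefqzError
from .fastq_io import ReferenceSequence
from .kmer_index import KmerIndex, MappingParams, hash_kmer

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")

# re-synchronization window probed when choosing between S/D/I at a mismatch
RESYNC_WINDOW = 8
# longest insertion/deletion gap probed as a single event run
MAX_GAP = 5


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (N maps to N); an involution."""
    return seq.translate(_RC_TABLE)[::-1]


@dataclass
class AlignmentSegment:
    """A maximal run of one alignment event.

    mtype is one of M (match, copy reference), S (substitution), I (insertion
    relative to the reference) or D (deletion).  ``mis_values`` carries the
    read bases for S and I segments (length == mlength) and is empty for
    M and D.
    """

    mlength: int
    mtype: str
    mis_values: str = ""


@dataclass
class ReadMapping:
    """Mapping of a read (or fragment): position, segments, optional tail.

    ``pos == 0`` marks an unmapped fragment stored verbatim in ``raw``.
    ``pal`` means the fragment (including its own tail) encodes the reverse
    complement of the read piece it covers.  ``corrections`` are delta-coded
    residual fixes: the first entry is an absolute 1-based read position, each
    subsequent entry an offset from the previous one, paired with the true
    base.
    """

    pos: int
    pal: bool = False
    segments: list[AlignmentSegment] = field(default_factory=list)
    raw: str | None = None
    tail: "ReadMapping | None" = None
    corrections: list[tuple[int, str]] = field(default_factory=list)


def collect_votes(read: str, index: KmerIndex) -> dict[int, int]:
    """Candidate start positions and their seed vote counts.

    A k-mer at 0-based read offset ``j`` occurring at 1-based reference
    position ``p`` votes for candidate position ``p - j``; candidates < 1
    are discarded.
    """
    k = index.k
    votes: dict[int, int] = {}
    limit = len(read) - k
    j = read.find("CG")
    while j != -1 and j <= limit:
        key = hash_kmer(read[j : j + k], k)
        if key is not None:
            for p in index.positions(key):
                cand = p - j
                if cand >= 1:
                    votes[cand] = votes.get(cand, 0) + 1
        j = read.find("CG", j + 1)
    return votes


def _resync_score(read: str, ri: int, seq: str, gj: int, w: int = RESYNC_WINDOW) -> int:
    score = 0
    for d in range(w):
        if ri + d >= len(read) or gj + d >= len(seq):
            break
        if read[ri + d] == seq[gj + d]:
            score += 1
    return score


def local_align(
    read: str, ref: ReferenceSequence, pos: int, params: MappingParams
) -> tuple[list[AlignmentSegment], int, int, int]:
    """Greedy base-by-base extension of ``read`` against ``ref`` from ``pos``.

    Returns ``(segments, aligned_read_length, mismatch_count, consumed)``
    where ``aligned_read_length`` counts read bases covered (M+S+I) and
    ``consumed`` counts all alignment columns (M+S+I+D).  Extension stops
    before the running mismatch fraction ``mismatch_count / consumed`` would
    exceed ``params.e``, or at the end of the read or reference.  A
    zero-length alignment is a valid result.
    """
    if not 1 <= pos <= len(ref.seq):
        raise RefqzError(f"alignment position {pos} outside reference")
    seq = ref.seq
    n, m = len(read), len(seq)
    ri, gj = 0, pos - 1
    events: list[tuple[str, str]] = []  # (mtype, read base or "")
    mis = 0
    consumed = 0
    e = params.e
    while ri < n and gj < m:
        if read[ri] == seq[gj]:
            events.append(("M", ""))
            ri += 1
            gj += 1
            consumed += 1
            continue
        # probe substitution and indel gaps of 1..MAX_GAP bases; keep the
        # event run whose following bases re-synchronize best
        # (tie order: S, then D, then I; shorter gaps first)
        options = [("S", 1, _resync_score(read, ri + 1, seq, gj + 1))]
        for g in range(1, min(MAX_GAP, m - gj) + 1):
            options.append(("D", g, _resync_score(read, ri, seq, gj + g)))
        for g in range(1, min(MAX_GAP, n - ri) + 1):
            options.append(("I", g, _resync_score(read, ri + g, seq, gj)))
        kind, gap, _ = max(options, key=lambda o: o[2])
        if (mis + gap) > e * (consumed + gap):
            break
        if kind == "S":
            events.append(("S", read[ri]))
            ri += 1
            gj += 1
        elif kind == "D":
            events.extend(("D", "") for _ in range(gap))
            gj += gap
        else:
            for _ in range(gap):
                events.append(("I", read[ri]))
                ri += 1
        mis += gap
        consumed += gap
    # trailing S/I/D events give no evidence of re-synchronization; trim them
    # so the alignment always ends on a match
    while events and events[-1][0] != "M":
        t, _ = events.pop()
        mis -= 1
        consumed -= 1
        if t in ("S", "I"):
            ri -= 1
    segments: list[AlignmentSegment] = []
    for t, base in events:
        if segments and segments[-1].mtype == t:
            segments[-1].mlength += 1
            segments[-1].mis_values += base
        else:
            segments.append(AlignmentSegment(1, t, base))
    aligned = ri
    return segments, aligned, mis, consumed


def _align_best(
    read: str, ref: ReferenceSequence, candidates: list[int], params: MappingParams
) -> tuple[int, list[AlignmentSegment], int, int, int]:
    """Align at every tied candidate, keep the most matched bases, then the
    smallest position."""
    best = None
    for pos in sorted(candidates):
        segments, aligned, mis, consumed = local_align(read, ref, pos, params)
        matched = aligned - sum(s.mlength for s in segments if s.mtype in ("S", "I"))
        if best is None or matched > best[0]:
            best = (matched, pos, segments, aligned, mis, consumed)
    assert best is not None
    return best[1], best[2], best[3], best[4], best[5]


def map_read(
    read: str,
    ref: ReferenceSequence,
    index: KmerIndex,
    params: MappingParams,
    depth: int = 0,
) -> ReadMapping:
    """Map one read (or fragment); ``depth`` 1 marks the palindrome re-entry."""
    if depth not in (0, 1):
        raise ValueError("depth must be 0 or 1")
    if len(read) < params.k:
        return ReadMapping(pos=0, raw=read)
    votes = collect_votes(read, index)
    if not votes:
        return ReadMapping(pos=0, raw=read)
    maxv = max(votes.values())
    candidates = [p for p, v in votes.items() if v == maxv]
    pos, segments, aligned, mis, consumed = _align_best(read, ref, candidates, params)

    if aligned == 0:
        if depth == 1:
            return ReadMapping(pos=0, raw=read)
        sub = map_read(reverse_complement(read), ref, index, params, depth=1)
        if sub.pos == 0 and sub.tail is None:
            return ReadMapping(pos=0, raw=read)
        return replace(sub, pal=True)

    if depth == 1 and aligned < params.L:
        # a fragment failing at the palindrome re-entry is emitted raw
        return ReadMapping(pos=0, raw=read)

    head = ReadMapping(pos=pos, segments=segments)
    remainder = read[aligned:]
    if remainder:
        if depth == 0 and len(remainder) >= params.k:
            tail = map_read(reverse_complement(remainder), ref, index, params, depth=1)
            if tail.pos == 0 and tail.tail is None:
                head.tail = ReadMapping(pos=0, raw=remainder)
            else:
                tail.pal = True
                head.tail = tail
        else:
            head.tail = ReadMapping(pos=0, raw=remainder)
    return head


def reconstruct(mapping: ReadMapping, ref: ReferenceSequence) -> str:
    """Rebuild the read a mapping encodes (before corrections).

    Walks the reference from POS: M copies, S/I take their stored bases, D
    skips reference bases.  A pal-flagged fragment is reverse-complemented
    after its own tail has been appended, mirroring how the mapper split it.
    """
    if mapping.pos == 0:
        s = mapping.raw or ""
    else:
        seq = ref.seq
        gj = mapping.pos - 1
        parts: list[str] = []
        for seg in mapping.segments:
            if seg.mtype == "M":
                if gj + seg.mlength > len(seq):
                    raise CorruptArchiveError("alignment overruns the reference")
                parts.append(seq[gj : gj + seg.mlength])
                gj += seg.mlength
            elif seg.mtype == "S":
                if gj + seg.mlength > len(seq):
                    raise CorruptArchiveError("alignment overruns the reference")
                parts.append(seg.mis_values)
                gj += seg.mlength
            elif seg.mtype == "I":
                parts.append(seg.mis_values)
            elif seg.mtype == "D":
                gj += seg.mlength
                if gj > len(seq):
                    raise CorruptArchiveError("alignment overruns the reference")
            else:
                raise CorruptArchiveError(f"unknown segment type {seg.mtype!r}")
        s = "".join(parts)
    if mapping.tail is not None:
        s += reconstruct(mapping.tail, ref)
    if mapping.pal:
        s = reverse_complement(s)
    return s


def apply_corrections(read: str, corrections: list[tuple[int, str]]) -> str:
    """Apply delta-coded corrections to a reconstructed read."""
    if not corrections:
        return read
    chars = list(read)
    pos = 0
    for delta, base in corrections:
        pos += delta
        if not 1 <= pos <= len(chars):
            raise CorruptArchiveError(f"correction position {pos} outside read")
        chars[pos - 1] = base
    return "".join(chars)


def verify_and_correct(
    read: str, mapping: ReadMapping, ref: ReferenceSequence
) -> ReadMapping:
    """Compare the reconstruction with the original read and attach corrections.

    The mapper is allowed to emit approximate matches; losslessness is
    restored here.  A reconstruction of the wrong *length* indicates a bug in
    the mapper and is a hard error, never silently patched.
    """
    recon = reconstruct(mapping, ref)
    if len(recon) != len(read):
        raise RefqzError(
            f"internal error: reconstruction length {len(recon)} != read length {len(read)}"
        )
    corrections: list[tuple[int, str]] = []
    prev = 0
    for i, (a, b) in enumerate(zip(recon, read), start=1):
        if a != b:
            corrections.append((i - prev, b))
            prev = i
    mapping.corrections = corrections
    return mapping
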