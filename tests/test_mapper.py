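"""Seed voting, greedy alignment, palindrome fallback, correction pass."""

import pytest

from conftest import random_seq
from refqz.fastq_io import ReferenceSequence
from refqz.kmer_index import MappingParams, build_index
from refqz.mapper import (
    AlignmentSegment,
    ReadMapping,
    apply_corrections,
    collect_votes,
    local_align,
    map_read,
    reconstruct,
    reverse_complement,
    verify_and_correct,
)


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", "ACGT"), ("AACG", "CGTT"), ("N", "N"), ("", "")],
)
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


def test_reverse_complement_involution(rng):
    for _ in range(20):
        s = random_seq(rng, 50, alphabet="ACGTN")
        assert reverse_complement(reverse_complement(s)) == s


def brute_force_votes(read, ref_seq, k):
    """Oracle: enumerate all CG-prefixed N-free k-mers of the read and all
    their occurrences in the reference."""
    votes = {}
    for j in range(len(read) - k + 1):
        kmer = read[j : j + k]
        if not kmer.startswith("CG") or "N" in kmer:
            continue
        start = 0
        while True:
            p = ref_seq.find(kmer, start)
            if p == -1:
                break
            cand = p + 1 - j
            if cand >= 1:
                votes[cand] = votes.get(cand, 0) + 1
            start = p + 1
    return votes


def test_votes_empty_without_cg(small_index):
    assert collect_votes("ATTATTATTATTATT", small_index) == {}


def test_votes_match_brute_force(small_ref, small_index, params):
    read = small_ref.seq[10:40]  # positions 11..40
    votes = collect_votes(read, small_index)
    assert votes == brute_force_votes(read, small_ref.seq, params.k)
    if votes:
        assert max(votes, key=votes.get) == 11


def test_chimeric_read_produces_two_vote_clusters(small_ref, small_index, params):
    big = small_ref.seq[1000:1070]  # 70 bases at 1001
    small = small_ref.seq[5000:5030]  # 30 bases at 5001
    read = big + small
    votes = collect_votes(read, small_index)
    oracle = brute_force_votes(read, small_ref.seq, params.k)
    assert votes == oracle
    assert max(votes, key=votes.get) == 1001


def test_local_align_exact(small_ref, params):
    read = small_ref.seq[200:300]
    segments, aligned, mis, consumed = local_align(read, small_ref, 201, params)
    assert segments == [AlignmentSegment(100, "M")]
    assert (aligned, mis, consumed) == (100, 0, 100)


def test_local_align_one_substitution(small_ref, params):
    window = small_ref.seq[200:300]
    pos = 50
    sub = "ACGT"[("ACGT".index(window[pos]) + 1) % 4]
    read = window[:pos] + sub + window[pos + 1 :]
    segments, aligned, mis, consumed = local_align(read, small_ref, 201, params)
    assert [s.mtype for s in segments] == ["M", "S", "M"]
    assert segments[1].mis_values == sub
    assert (aligned, mis) == (100, 1)


def test_local_align_two_base_insertion(small_ref, params):
    window = small_ref.seq[300:380]
    read = window[:40] + "TA" + window[40:]
    # guard against the inserted bases accidentally matching the reference
    if small_ref.seq[340] == "T":
        read = window[:40] + "CA" + window[40:]
    segments, aligned, mis, consumed = local_align(read, small_ref, 301, params)
    types = [s.mtype for s in segments]
    assert types == ["M", "I", "M"]
    assert segments[1].mlength == 2
    assert aligned == len(read)


def test_local_align_respects_mismatch_budget(small_ref, params):
    # a read unrelated to the window: alignment must stop almost immediately
    read = reverse_complement(small_ref.seq[600:700])
    segments, aligned, mis, consumed = local_align(read, small_ref, 201, params)
    if consumed:
        assert mis / consumed <= params.e


def test_map_read_exact(small_ref, small_index, params):
    read = small_ref.seq[500:600]
    m = map_read(read, small_ref, small_index, params)
    assert m.pos == small_ref.seq.find(read) + 1
    assert m.segments == [AlignmentSegment(100, "M")]
    assert m.tail is None and not m.pal


def test_map_read_unmappable_is_raw(small_ref, small_index, params):
    read = "T" * 40
    m = map_read(read, small_ref, small_index, params)
    assert (m.pos, m.raw) == (0, read)


def test_map_read_chimeric_palindrome_tail(small_ref, small_index, params):
    head = small_ref.seq[99:149]  # 1-based 100..149
    tail = reverse_complement(small_ref.seq[299:349])  # RC of 300..349
    read = head + tail
    m = map_read(read, small_ref, small_index, params)
    assert m.pos == 100
    assert m.tail is not None and m.tail.pal
    assert m.tail.pos == 300
    corrected = verify_and_correct(read, m, small_ref)
    assert apply_corrections(reconstruct(corrected, small_ref), corrected.corrections) == read


def test_mapped_fragments_respect_mismatch_rate(small_ref, small_index, params, rng):
    for _ in range(50):
        start = int(rng.integers(0, len(small_ref.seq) - 120))
        window = list(small_ref.seq[start : start + 100])
        for _ in range(2):  # two random substitutions
            i = int(rng.integers(0, 100))
            window[i] = "ACGT"[int(rng.integers(0, 4))]
        read = "".join(window)
        m = map_read(read, small_ref, small_index, params)
        frag = m
        while frag is not None:
            if frag.pos != 0:
                mis = sum(s.mlength for s in frag.segments if s.mtype in "SID")
                consumed = sum(s.mlength for s in frag.segments)
                assert mis / consumed <= params.e
            frag = frag.tail


def test_verify_and_correct_delta_example(small_ref):
    """Residual mismatches at read positions 16 and 23 delta-code as 16A7C."""
    window = small_ref.seq[50:80]
    read = list(window)
    read[15] = "A" if window[15] != "A" else "T"
    read[22] = "C" if window[22] != "C" else "G"
    read = "".join(read)
    # a deliberately approximate mapping: plain match over the whole window
    mapping = ReadMapping(pos=51, segments=[AlignmentSegment(30, "M")])
    corrected = verify_and_correct(read, mapping, small_ref)
    assert corrected.corrections == [(16, read[15]), (7, read[22])]
    assert apply_corrections(reconstruct(corrected, small_ref), corrected.corrections) == read


def test_verify_and_correct_exact_is_empty(small_ref, small_index, params):
    read = small_ref.seq[700:800]
    m = verify_and_correct(read, map_read(read, small_ref, small_index, params), small_ref)
    assert m.corrections == []


def test_corrections_repair_random_edits(small_ref, rng):
    for _ in range(100):
        start = int(rng.integers(0, len(small_ref.seq) - 60))
        window = small_ref.seq[start : start + 50]
        mapping = ReadMapping(pos=start + 1, segments=[AlignmentSegment(50, "M")])
        read = list(window)
        for _ in range(int(rng.integers(0, 6))):
            read[int(rng.integers(0, 50))] = "ACGTN"[int(rng.integers(0, 5))]
        read = "".join(read)
        m = verify_and_correct(read, mapping, small_ref)
        assert apply_corrections(reconstruct(m, small_ref), m.corrections) == read


def test_lossless_on_random_reads(small_ref, small_index, params, rng):
    """Every read decodes byte-exactly, mapped or not."""
    for _ in range(200):
        n = int(rng.integers(1, 150))
        if rng.random() < 0.5:
            start = int(rng.integers(0, len(small_ref.seq) - n))
            read = small_ref.seq[start : start + n]
        else:
            read = random_seq(rng, n, alphabet="ACGTN")
        m = verify_and_correct(read, map_read(read, small_ref, small_index, params), small_ref)
        assert apply_corrections(reconstruct(m, small_ref), m.corrections) == read
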