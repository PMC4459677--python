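"""k-mer hash index of the reference (seed table for the mapper).

Only k-mers whose first two bases are ``CG`` are indexed — the most common
dimer — trading seed sensitivity for a small, fast table.  Keys are the
2-bit-per-base packing of the k-mer (A=00, C=01, G=10, T=11), so the table is
a plain dict from integer key to the ascending list of 1-based reference
positions.  k-mers overlapping an ``N`` are skipped both at build and query
time, since the 2-bit alphabet cannot represent them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import RefqzError
from .fastq_io import ReferenceSequence

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"

MAX_K = 16  # 2k bits must fit comfortably in a machine integer


@dataclass(frozen=True)
class MappingParams:
    """Tunable mapping parameters.

    k
        seed k-mer length (default 10).
    L
        minimum aligned read length for a fragment to count as mapped
        (default 12).
    e
        maximum tolerated mismatch fraction during alignment extension
        (default 0.05).
    """

    k: int = 10
    L: int = 12
    e: float = 0.05

    def __post_init__(self) -> None:
        if not 3 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [3, {MAX_K}], got {self.k}")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0.0 <= self.e < 1.0:
            raise ValueError("e must be in [0, 1)")


def hash_kmer(kmer: str, k: int) -> int | None:
    """2-bit pack a k-mer into its integer key; ``None`` if it is unhashable.

    Returns ``None`` for any k-mer containing a base outside {A,C,G,T}
    (the caller simply skips that seed).
    """
    if len(kmer) != k:
        raise ValueError(f"expected a {k}-mer, got {len(kmer)} bases")
    key = 0
    for c in kmer:
        code = _CODE.get(c)
        if code is None:
            return None
        key = (key << 2) | code
    return key


def unhash_kmer(key: int, k: int) -> str:
    """Inverse of :func:`hash_kmer` (used for self-consistency checks)."""
    bases = []
    for shift in range(2 * (k - 1), -2, -2):
        bases.append(_BASE[(key >> shift) & 3])
    return "".join(bases)


@dataclass
class KmerIndex:
    """Hash table from 2-bit k-mer key to ascending 1-based reference positions."""

    k: int
    table: dict[int, list[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def positions(self, key: int) -> list[int]:
        return self.table.get(key, [])


def build_index(ref: ReferenceSequence, params: MappingParams) -> KmerIndex:
    """Scan the reference once and index every CG-prefixed, N-free k-mer."""
    k = params.k
    seq = ref.seq
    if len(seq) < k:
        raise RefqzError(f"reference ({len(seq)} bases) is shorter than k = {k}")
    index = KmerIndex(k=k)
    table = index.table
    limit = len(seq) - k
    i = seq.find("CG")
    while i != -1 and i <= limit:
        kmer = seq[i : i + k]
        key = hash_kmer(kmer, k)
        if key is not None:  # skip k-mers overlapping an N
            table.setdefault(key, []).append(i + 1)  # 1-based
        i = seq.find("CG", i + 1)
    return index
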