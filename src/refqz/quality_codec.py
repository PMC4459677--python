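"""Run-length-limited (RLL) coding of quality strings.

Quality strings are byte sequences in the printable range [33, 126], rich in
runs of the same character.  Only runs of length n > 2 are tokenized: the run
character is emitted with its 8th bit flipped on (``byte | 0x80``), followed
by one length byte storing ``n - 1``, capping a run at 256 (longer runs are
split).  Characters outside runs are emitted as plain literals.

A block of at least four consecutive runs strictly alternating between two
characters X and Y (X first, Y last) is further simplified: flagged X with
its length, the bare length bytes of the interior runs, then flagged Y with
the final length.  The decoder infers the interior characters by alternation.
To keep the stream prefix-free without any extra framing byte, interior runs
are restricted to n in [3, 33]: their stored bytes (2..32) can never collide
with a literal (>= 33) or a flagged byte (>= 128).  Blocks with longer
interior runs simply pass through unsimplified.
"""

from __future__ import annotations

from .errors import CorruptArchiveError, RefqzError

MAX_RUN = 256  # 8-bit length byte stores n - 1
MIN_RUN = 3  # only runs of n > 2 are flagged
MAX_INTERIOR_RUN = 33  # interior length bytes must stay below the literal range
MIN_ALT_BLOCK = 4  # minimum number of runs in an alternation block

# token forms:
#   ("lit", char)
#   ("run", char, n)                  with 3 <= n <= 256
#   ("alt", x, y, [n1, ..., nm])      m even, >= 4; interior n in [3, 33]
Token = tuple


def tokenize(quality: str) -> list[Token]:
    """Split a quality string into literal and run tokens (no simplification)."""
    tokens: list[Token] = []
    i = 0
    n = len(quality)
    while i < n:
        c = quality[i]
        b = ord(c)
        if not 33 <= b <= 126:
            raise RefqzError(
                f"quality byte {b} at offset {i} outside printable range [33, 126]"
            )
        j = i + 1
        while j < n and quality[j] == c:
            j += 1
        run = j - i
        while run >= MIN_RUN:
            chunk = min(run, MAX_RUN)
            if run - chunk in (1, 2) and chunk == MAX_RUN:
                # avoid leaving a sub-minimal remainder after a split
                chunk = run - MIN_RUN
            tokens.append(("run", c, chunk))
            run -= chunk
        tokens.extend(("lit", c) for _ in range(run))
        i = j
    return tokens


def simplify_alternation(tokens: list[Token]) -> list[Token]:
    """Rewrite eligible alternating-run blocks into ``alt`` tokens.

    Never increases the symbol count: a block of m runs costs m + 2 symbols
    instead of 2m.
    """
    out: list[Token] = []
    i = 0
    n = len(tokens)
    while i < n:
        if tokens[i][0] != "run":
            out.append(tokens[i])
            i += 1
            continue
        # maximal stretch of run tokens strictly alternating between two chars
        j = i + 1
        while (
            j < n
            and tokens[j][0] == "run"
            and tokens[j][1] != tokens[j - 1][1]
            and (j - i < 2 or tokens[j][1] == tokens[j - 2][1])
        ):
            j += 1
        block = tokens[i:j]
        if len(block) % 2 == 1:
            block = block[:-1]  # must end on the second character
        if len(block) >= MIN_ALT_BLOCK and all(
            t[2] <= MAX_INTERIOR_RUN for t in block[1:-1]
        ):
            out.append(("alt", block[0][1], block[1][1], [t[2] for t in block]))
            i += len(block)
        else:
            out.append(tokens[i])
            i += 1
    return out


def encode_tokens(tokens: list[Token]) -> bytes:
    """Serialize tokens to the RLL byte stream (one 8-bit symbol per element)."""
    out = bytearray()
    for t in tokens:
        if t[0] == "lit":
            out.append(ord(t[1]))
        elif t[0] == "run":
            _, c, n = t
            if not MIN_RUN <= n <= MAX_RUN:
                raise RefqzError(f"run length {n} outside [{MIN_RUN}, {MAX_RUN}]")
            out.append(ord(c) | 0x80)
            out.append(n - 1)
        else:
            _, x, y, lengths = t
            if len(lengths) < MIN_ALT_BLOCK or len(lengths) % 2:
                raise RefqzError("malformed alternation block")
            out.append(ord(x) | 0x80)
            out.append(lengths[0] - 1)
            for v in lengths[1:-1]:
                if not MIN_RUN <= v <= MAX_INTERIOR_RUN:
                    raise RefqzError(f"interior run length {v} not encodable")
                out.append(v - 1)
            out.append(ord(y) | 0x80)
            out.append(lengths[-1] - 1)
    return bytes(out)


def rll_encode(quality: str) -> bytes:
    """Full RLL encoding: tokenize, simplify alternating blocks, serialize."""
    return encode_tokens(simplify_alternation(tokenize(quality)))


def rll_decode(stream: bytes) -> str:
    """Exact inverse of :func:`rll_encode`."""
    out: list[str] = []
    i = 0
    n = len(stream)
    while i < n:
        b = stream[i]
        if b < 0x80:
            if b < 33:
                raise CorruptArchiveError(f"stray length byte {b} at offset {i}")
            out.append(chr(b))
            i += 1
            continue
        x = chr(b & 0x7F)
        i += 1
        if i >= n:
            raise CorruptArchiveError("truncated run token at end of stream")
        n1 = stream[i] + 1
        i += 1
        if n1 < MIN_RUN:
            raise CorruptArchiveError(f"run of length {n1} should not be flagged")
        interior: list[int] = []
        while i < n and stream[i] < 33:
            interior.append(stream[i] + 1)
            i += 1
        if not interior:
            out.append(x * n1)
            continue
        # alternation block: must close with a flagged second character
        if i + 1 >= n or stream[i] < 0x80:
            raise CorruptArchiveError("alternation block not closed by a flagged run")
        y = chr(stream[i] & 0x7F)
        nm = stream[i + 1] + 1
        i += 2
        if y == x or len(interior) % 2 or nm < MIN_RUN or any(v < MIN_RUN for v in interior):
            raise CorruptArchiveError("malformed alternation block")
        lengths = [n1, *interior, nm]
        for idx, run_len in enumerate(lengths):
            out.append((x if idx % 2 == 0 else y) * run_len)
    return "".join(out)
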