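"""Exception hierarchy shared across the codec modules."""


class RefqzError(Exception):
    """Base class for all refqz errors."""


class FastqFormatError(RefqzError):
    """The input FASTQ byte stream is malformed (truncated record, bad line)."""


class FastaFormatError(RefqzError):
    """The reference FASTA could not be parsed."""


class CorruptArchiveError(RefqzError):
    """An archive payload failed to decode (bad grammar, overrun, bad length)."""


class ReferenceMismatchError(RefqzError):
    """The reference supplied at decompression is not the one used to compress."""
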