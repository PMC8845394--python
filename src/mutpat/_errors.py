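"""Exception hierarchy shared across the package."""


class MutpatError(Exception):
    """Base class for all errors raised by mutpat."""


class ContigMissingError(MutpatError):
    """A contig referenced by a variant or region is absent from the genome."""


class ChannelMismatchError(MutpatError):
    """Two matrices do not share an identical, identically ordered channel set."""


class AmbiguousContextError(MutpatError):
    """A mutation context overlaps an ambiguous (N) reference base."""
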