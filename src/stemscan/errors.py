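"""Exception hierarchy shared across stemscan modules."""


class StemscanError(Exception):
    """Base class for all stemscan-specific failures."""


class FastaFormatError(StemscanError):
    """Raised when a FASTA file is empty or malformed; names the offending line."""


class BoundsError(StemscanError, ValueError):
    """A 1-based inclusive interval falls outside a record's coordinate range."""


class AssemblyError(StemscanError):
    """Two oligonucleotides share no unique complementary 3' overlap."""


class AlphabetError(StemscanError, ValueError):
    """A residue outside {A, C, G, U} (or the DNA equivalent) was encountered."""


class ConfigError(StemscanError, ValueError):
    """An operation was configured with an invalid parameter."""


class ComparisonError(StemscanError):
    """Two sequences cannot be compared (e.g. unequal lengths)."""
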