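"""Exception types shared across the package."""


class IntroscanError(Exception):
    """Base class for all package errors."""


class ConfigError(IntroscanError, ValueError):
    """Invalid configuration or parameter value."""


class FormatError(IntroscanError, ValueError):
    """Malformed input file (VCF, popmap, Newick, FASTA)."""


class ReferenceLookupError(IntroscanError, KeyError):
    """A named individual, group, or taxon does not exist."""


class ConsistencyError(IntroscanError, ValueError):
    """Inputs are individually valid but mutually inconsistent."""


class PreconditionError(IntroscanError, ValueError):
    """A documented operation precondition does not hold."""


class DegenerateTreeError(IntroscanError, ValueError):
    """Tree has no usable branch-length structure (e.g. zero depth)."""
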