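"""Package-wide exception types."""


class MetaboconstraintError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MetaboconstraintError, ValueError):
    """A generator or operation was called with out-of-range parameters."""


class FormatError(MetaboconstraintError, ValueError):
    """An input file or in-memory object violates its format contract."""


class TranslationError(MetaboconstraintError, ValueError):
    """A CDS does not translate to its protein alignment row."""


class ExternalToolError(MetaboconstraintError, RuntimeError):
    """An external binary (codeml, muscle, mafft) is unavailable or failed."""
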