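"""Exception hierarchy for the pipeline.

Every error raised on purpose derives from :class:`PdxResistError` so callers
(and the CLI) can distinguish pipeline diagnostics from programming bugs.
"""


class PdxResistError(Exception):
    """Base class for all pipeline errors."""


class ParseError(PdxResistError):
    """A record in an input file could not be parsed; the message names the line."""


class ValidationError(PdxResistError):
    """An input value violates a data-type invariant (e.g. alt_reads > total_reads)."""


class RoleMappingError(PdxResistError):
    """A sample identifier in a file does not match any declared sample role."""


class ConfigurationError(PdxResistError):
    """The run configuration is incomplete or inconsistent (e.g. missing germline role)."""


class UndefinedAlleleFractionError(PdxResistError):
    """Allele fraction requested at a locus with zero total reads."""


class ContractError(PdxResistError):
    """An operation was called outside its stated precondition."""
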