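"""Exception hierarchy shared across the pipeline.

All pipeline errors derive from :class:`DecidiffError` so callers can catch
one base class; subclasses distinguish malformed input files, inconsistent
study designs, invalid numeric domains, and empty selections.
"""


class DecidiffError(Exception):
    """Base class for all decidiff errors."""


class FormatError(DecidiffError, ValueError):
    """An external file violates its documented format or invariants."""


class DesignError(DecidiffError, ValueError):
    """A study design is inconsistent with the expression data."""


class DomainError(DecidiffError, ValueError):
    """A numeric or set-valued argument is outside its valid domain."""


class EmptySelectionError(DecidiffError, ValueError):
    """A filter selected zero cells/genes where at least one is required."""


class ConfigError(DecidiffError, ValueError):
    """A simulation or run configuration is internally inconsistent."""
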