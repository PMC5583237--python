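"""Exception hierarchy shared across the package."""


class LodemapError(Exception):
    """Base class for package errors."""


class FormatError(LodemapError):
    """A file could not be parsed in the declared dialect."""


class IntegrityError(LodemapError):
    """Parsed data violates a structural invariant (duplicates, cross-reference gaps)."""


class ConfigError(LodemapError):
    """A simulation or pipeline configuration is invalid."""
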