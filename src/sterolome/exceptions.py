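"""Exception hierarchy for the sterolome package."""


class SterolomeError(Exception):
    """Base class for all package errors."""


class FormatError(SterolomeError):
    """An input file does not conform to the expected schema."""


class ParseError(SterolomeError):
    """A cell or token could not be parsed."""


class ConfigError(SterolomeError):
    """An invalid run configuration value."""


class DegenerateInputError(SterolomeError):
    """Input is structurally valid but statistically degenerate
    (e.g. all points identical, constant trait)."""
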