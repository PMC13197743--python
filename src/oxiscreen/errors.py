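"""Exception hierarchy shared across the package."""


class OxiscreenError(Exception):
    """Base class for all package errors."""


class FormatError(OxiscreenError):
    """A file could not be interpreted in the expected format."""


class DegenerateInputError(OxiscreenError):
    """Input is structurally readable but carries no analyzable content."""


class ContractError(OxiscreenError):
    """A documented precondition of an operation was violated."""


class ConfigurationError(OxiscreenError):
    """A run configuration is inconsistent or references unknown entities."""


class GenerationError(OxiscreenError):
    """Synthetic-signal generation could not satisfy its constraints."""


class FitError(OxiscreenError):
    """A statistical model failed to converge or was inestimable."""
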