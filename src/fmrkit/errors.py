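"""Exception types shared across the package."""


class FmrError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FmrError, ValueError):
    """Invalid configuration (bad MAF, negative sample size, unknown key...)."""


class DomainError(FmrError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ParseError(FmrError, ValueError):
    """Malformed input file; message names the offending column/line."""


class EstimationError(FmrError, RuntimeError):
    """An estimator cannot produce a result (empty instrument set, collinearity...)."""
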