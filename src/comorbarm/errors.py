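"""Exception hierarchy shared across the pipeline stages."""


class ComorbArmError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ComorbArmError):
    """A simulation or run configuration field is invalid."""


class FormatError(ComorbArmError):
    """A raw input value cannot be parsed into the expected shape."""


class ParameterError(ComorbArmError):
    """An operation was called with an out-of-range parameter."""


class ValidationError(ComorbArmError):
    """Input data violate a documented precondition."""


class ConsistencyError(ComorbArmError):
    """Internally inconsistent inputs (e.g. index date outside the data window)."""


class UndefinedRuleError(ComorbArmError):
    """A rule metric is undefined (zero antecedent support or zero lift sum)."""


class EmptyInputError(ComorbArmError):
    """An operation that requires data received an empty container."""
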