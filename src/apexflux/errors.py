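"""Exception hierarchy shared across the package."""


class ApexFluxError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ApexFluxError, ValueError):
    """A required column is missing or a field violates its schema."""


class DesignMismatchError(ApexFluxError, ValueError):
    """A sample in an input file is absent from the experiment design."""


class FormatError(ApexFluxError, ValueError):
    """A file is syntactically malformed (reported with line number)."""


class ConfigError(ApexFluxError, ValueError):
    """A parameter or configuration value is outside its documented range."""


class NormalizationError(ApexFluxError, ValueError):
    """A sample cannot be riBAQ-normalized (zero total iBAQ)."""


class UndefinedPsiError(ApexFluxError, ValueError):
    """PSI is undefined because inclusion + exclusion counts are zero."""


class ModelError(ApexFluxError, ValueError):
    """A junction model table is invalid (e.g. duplicate junction keys)."""
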