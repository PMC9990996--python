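"""Exception hierarchy for the cismr pipeline."""


class CismrError(Exception):
    """Base class for all cismr errors."""


class FormatError(CismrError):
    """A required column is missing or a file cannot be parsed."""


class EmptyInputError(CismrError):
    """An input table contained zero valid rows."""


class EmptyIntersectionError(CismrError):
    """Two summary-statistic sets share no reconcilable variants."""


class UndefinedRatioError(CismrError):
    """Wald ratio requested with a zero exposure effect."""


class CollinearityError(CismrError):
    """Conditional analysis target is (nearly) collinear with the condition set."""


class ConfigError(CismrError):
    """A scenario or run configuration is invalid."""


class DuplicateKeyError(CismrError):
    """Duplicate (gene, trait) or variant keys where uniqueness is required."""
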