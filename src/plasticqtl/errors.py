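"""Exception hierarchy for plasticqtl."""


class PlasticQtlError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(PlasticQtlError):
    """A delimited input file is malformed (missing header, bad columns)."""


class DataValidationError(PlasticQtlError):
    """Input parsed but violates a data-model invariant (e.g. non-biallelic code)."""


class InputError(PlasticQtlError):
    """Inputs are individually valid but mutually inconsistent (e.g. zero overlap)."""


class EmptyResultError(PlasticQtlError):
    """An operation removed everything (e.g. all markers filtered out)."""


class InsufficientDataError(PlasticQtlError):
    """Too few informative observations to compute the requested statistic."""


class UndefinedLinkageError(PlasticQtlError):
    """Recombination fraction or map distance is undefined (r >= 0.5, no informative pairs)."""


class ConfigError(PlasticQtlError):
    """A simulation or pipeline configuration is invalid."""
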