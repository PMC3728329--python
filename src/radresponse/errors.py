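"""Exception hierarchy shared across the pipeline stages."""


class RadResponseError(Exception):
    """Base class for all package errors."""


class ParameterError(RadResponseError, ValueError):
    """Invalid user-supplied parameter (fractions, counts, thresholds, levels)."""


class FormatError(RadResponseError, ValueError):
    """Malformed input file (ragged rows, duplicate IDs, non-numeric cells)."""


class DesignError(RadResponseError, ValueError):
    """Sample design inconsistent with the requested analysis."""


class DataError(RadResponseError, ValueError):
    """Data degenerate for the requested computation (all-zero variances, missing reference gene, ...)."""
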