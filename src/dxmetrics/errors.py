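"""Exception hierarchy shared across the package."""


class DxMetricsError(Exception):
    """Base class for all package errors."""


class InputError(DxMetricsError):
    """Malformed input data: unknown column, non-numeric value, negative count."""


class ConfigError(DxMetricsError):
    """Inconsistent analysis configuration (e.g. domain value without a domain column)."""


class EmptyTableError(DxMetricsError):
    """No usable rows remain after filtering and missing-value exclusion."""


class UndefinedMeasureError(DxMetricsError):
    """A measure is not estimable on this table (zero denominator, degenerate margins).

    Callers that assemble reports catch this and render the configured
    missing-value label instead of a number, preserving the distinction
    between "estimated as zero" and "not estimable".
    """


class UndefinedCurveError(DxMetricsError):
    """ROC/PR curve is undefined (truth labels all one class)."""
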