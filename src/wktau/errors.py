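"""Exception hierarchy.

All package-specific errors derive from :class:`WktauError` so callers can
catch one base class; validation errors additionally derive from
:class:`ValueError` where the problem is a bad argument.
"""


class WktauError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(WktauError, ValueError):
    """Invalid configuration (distribution spec, schema, experiment setup)."""


class DataError(WktauError, ValueError):
    """Input data unusable: empty/NaN samples, too few cycles, flat wave."""


class FitError(WktauError, RuntimeError):
    """A numerical fit failed or is ill-posed (non-decaying window,
    degenerate predictor, root bracketing failure)."""
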