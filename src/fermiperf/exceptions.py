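"""Exception hierarchy for the perfusion pipeline.

Every stage raises a subclass of :class:`FermiperfError` so callers can
distinguish pipeline failures from programming errors.
"""


class FermiperfError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FermiperfError, ValueError):
    """A model or configuration parameter is outside its documented range."""


class NonUniformSamplingError(FermiperfError, ValueError):
    """An operation requiring uniform temporal sampling received a
    non-uniform time grid; resample first."""


class RoiNotFoundError(FermiperfError, RuntimeError):
    """Automatic region-of-interest detection failed (e.g. the series is
    constant in time)."""


class ZeroVarianceError(FermiperfError, RuntimeError):
    """Correlation is undefined because one image has zero variance inside
    the region of interest."""


class DelineationError(FermiperfError, RuntimeError):
    """Automatic contour delineation failed; the caller may supply manual
    contours instead."""


class ContourValidationError(FermiperfError, ValueError):
    """Supplied contours are invalid (e.g. endocardium not inside
    epicardium)."""


class ConfigError(FermiperfError, ValueError):
    """Inconsistent pipeline or phantom configuration."""


class InputError(FermiperfError, ValueError):
    """Malformed data input (shape mismatch, empty mask, non-finite
    values...)."""


class FileFormatError(FermiperfError, ValueError):
    """A file on disk is malformed or a required companion file is
    missing; the message names the offending field."""
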