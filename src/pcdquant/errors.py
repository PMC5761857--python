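"""Typed exceptions raised across the package."""


class PCDQuantError(Exception):
    """Base class for all package errors."""


class ImageFormatError(PCDQuantError):
    """Input raster violates the expected format (non-square, RGB, unreadable...)."""


class DegenerateImageError(PCDQuantError):
    """Image content makes an operation meaningless (e.g. near-constant image)."""


class GeometryError(PCDQuantError):
    """ROI geometry is invalid or does not fit the image."""


class SimulationError(PCDQuantError):
    """A synthetic-data specification is invalid or unsatisfiable."""


class SingularDesignError(PCDQuantError):
    """Statistical design matrix is singular (e.g. a constant covariate)."""


class SchemaError(PCDQuantError):
    """A cohort table is missing required columns or has invalid values."""
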