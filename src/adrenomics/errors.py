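"""Exception hierarchy.

All library errors derive from :class:`AdrenomicsError`; the CLI maps them
to exit code 1 (user/input error) while anything else is an internal error.
"""


class AdrenomicsError(Exception):
    """Base class for all errors raised by this package."""


class MetadataError(AdrenomicsError):
    """Required image metadata is missing or inconsistent (names the field)."""


class GeometryError(AdrenomicsError):
    """Volume/mask grids or voxel spacings do not match."""


class EmptyVOIError(AdrenomicsError):
    """A volume of interest contains no voxels."""


class ParameterError(AdrenomicsError):
    """An operation parameter is out of its valid range."""


class SpecError(ParameterError):
    """A simulation spec is invalid or would produce a degenerate phantom."""


class DegenerateError(AdrenomicsError):
    """Input is too degenerate for the statistic to be defined."""


class UndefinedWashoutError(AdrenomicsError):
    """Washout denominator is zero."""


class SchemaError(AdrenomicsError):
    """A cohort table is missing required columns."""
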