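"""Exception hierarchy for dvhkit.

All domain errors derive from :class:`DVHKitError` so callers (and the CLI)
can catch one base class.
"""


class DVHKitError(Exception):
    """Base class for all dvhkit domain errors."""


class BundleMalformedError(DVHKitError):
    """The plan-bundle directory is missing or its header is unreadable."""


class GridInconsistentError(DVHKitError):
    """A dose-grid file is absent or disagrees with the header geometry."""


class DanglingStructureError(DVHKitError):
    """The header references a structure whose contour file cannot be resolved."""


class DegenerateContourError(DVHKitError):
    """A contour has no slices, or a ring with fewer than 3 vertices."""


class StructureOutsideGridError(DVHKitError):
    """No contour slice overlaps the dose grid."""


class EmptyStructureError(DVHKitError):
    """A rasterized structure contains no voxels."""


class CurveTooShortError(DVHKitError):
    """A cumulative DVH has too few samples to support windowed smoothing."""


class NoClosedFormError(DVHKitError):
    """The requested phantom configuration has no closed-form DVH."""


class PoiParseError(DVHKitError):
    """A DVH point-of-interest query token could not be parsed."""
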