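"""Exception hierarchy shared across the package."""


class CircdendroError(Exception):
    """Base class for all package errors."""


class SWCError(CircdendroError, ValueError):
    """Base class for SWC reading/writing problems."""


class SWCFormatError(SWCError):
    """Malformed SWC content (bad field count, non-numeric field, duplicate id)."""


class SWCConnectivityError(SWCError):
    """Parent references that do not resolve, or cyclic parent chains."""


class EmptyMorphologyError(SWCError):
    """An operation that requires at least one tracing point got none."""


class DegenerateGeometryError(CircdendroError, ValueError):
    """Geometry too degenerate for the requested computation (e.g. collinear cloud)."""


class LayoutError(CircdendroError, ValueError):
    """Invalid layout request (zero terminals, non-positive weight, bad mode)."""


class FeatureError(CircdendroError, ValueError):
    """A feature key is unknown or not defined where it is required."""


class SpineError(CircdendroError, ValueError):
    """A spine record is inconsistent with the branch it references."""
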