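"""Exception types shared across the package."""


class RamanTagError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RamanTagError, ValueError):
    """A file or in-memory object violates an expected format.

    The message always names the offending location (channel index,
    line number, or dataset) so malformed input is locatable.
    """


class GeometryError(RamanTagError, ValueError):
    """A phantom geometry specification violates a containment invariant."""


class AxisError(RamanTagError, ValueError):
    """A requested spectral window or section falls outside the axis."""
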