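"""Exception hierarchy shared across the package."""


class AtrifocusError(Exception):
    """Base class for all package-specific errors."""


class InvalidWindowError(AtrifocusError):
    """Baseline window lies outside the trace or holds too few samples."""


class EmptyTraceError(AtrifocusError):
    """Operation requires a non-empty signal."""


class InvalidMeasurementError(AtrifocusError):
    """Peak measurement violates its invariants (negative amplitudes)."""


class MissingLeadError(AtrifocusError):
    """A layout lead has no corresponding trace/label."""

    def __init__(self, missing, extra=()):
        self.missing = sorted(missing)
        self.extra = sorted(extra)
        msg = f"missing leads: {self.missing}"
        if self.extra:
            msg += f"; unexpected leads: {self.extra}"
        super().__init__(msg)


class LayoutMismatchError(AtrifocusError):
    """Lead sets differ between frames, or a lead id is unknown to the layout."""


class DegenerateLayoutError(AtrifocusError):
    """Electrode layout leaves at least one torso quadrant empty."""


class AssignmentMismatchError(AtrifocusError):
    """A polarity-map lead is absent from the quadrant assignment."""


class UnresolvableTieError(AtrifocusError):
    """Tied quadrant scores admit no discriminating neighbour comparison."""


class InvalidWinnerError(AtrifocusError):
    """Sub-quadrant refinement asked for a quadrant that is not a maximum."""


class MissingVariantError(AtrifocusError):
    """Requested atrial-position variant absent from the correlation table."""


class InvalidGeometryError(AtrifocusError):
    """Degenerate mesh/geometry parameters."""


class UnreachableVertexError(AtrifocusError):
    """Mesh is disconnected: some vertices are unreachable from the focus."""


class SingularGeometryError(AtrifocusError):
    """An electrode coincides with a source position."""


class ConfigurationError(AtrifocusError):
    """Invalid or incomplete run configuration."""


class ParseError(AtrifocusError):
    """Malformed input file; message carries location detail."""


class SchemaError(AtrifocusError):
    """Structured-text document violates its schema."""
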