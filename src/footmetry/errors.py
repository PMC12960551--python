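"""Exception hierarchy used across footmetry."""


class FootmetryError(Exception):
    """Base class for all domain errors raised by footmetry."""


class MeshFormatError(FootmetryError):
    """Mesh file is malformed or violates mesh invariants."""


class LandmarkSchemaError(FootmetryError):
    """Landmark file violates the documented id/coordinate schema."""


class DegenerateGeometryError(FootmetryError):
    """Input geometry is degenerate (collinear/coincident points, zero area)."""


class GeometryError(FootmetryError):
    """A geometric construction failed (missed chord, negative length, ...)."""


class EmptyTraceError(GeometryError):
    """No mesh faces lie below the plantar-trace height cutoff."""


class OpenSectionError(GeometryError):
    """A plane--mesh intersection produced no closed loop."""


class MissingLandmarkError(FootmetryError):
    """An operation requires a landmark that is not present."""


class MeasurementError(FootmetryError):
    """A measurement sub-operation failed; carries the measurement name."""

    def __init__(self, measurement: str, message: str):
        self.measurement = measurement
        super().__init__(f"{measurement}: {message}")


class DegenerateVarianceError(FootmetryError):
    """Rating table has zero total variance; ICC is undefined."""


class InvalidDesignError(FootmetryError):
    """A sample-size or study-design specification is invalid."""


class MissingCellError(FootmetryError):
    """A rating panel is missing required subject/rater/repetition cells."""

    def __init__(self, cells, message: str | None = None):
        self.cells = list(cells)
        super().__init__(message or f"missing cells: {self.cells}")
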