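"""Exception hierarchy.

All package errors derive from :class:`GpcrActivityError` so callers can
catch everything with one clause; each also derives from the closest
builtin (ValueError/KeyError/RuntimeError) so generic handling keeps
working.
"""


class GpcrActivityError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GpcrActivityError, ValueError):
    """A file could not be parsed in the expected format."""


class ConsistencyError(GpcrActivityError, ValueError):
    """Inputs are individually valid but mutually inconsistent
    (duplicate BW positions, topology/trajectory atom-count mismatch...)."""


class OutOfRangeError(GpcrActivityError, ValueError):
    """A value lies outside its documented range (activity outside
    [0, 100], model index beyond the file, k > number of rows...)."""


class MissingFeatureError(GpcrActivityError, KeyError):
    """One or more BW positions or atoms required by the feature schema
    could not be resolved in a structure frame.

    ``positions`` lists every unresolvable BW position, not just the first.
    """

    def __init__(self, positions, message=None):
        self.positions = tuple(positions)
        msg = message or "unresolvable BW positions: " + ", ".join(self.positions)
        super().__init__(msg)

    def __str__(self):  # KeyError would repr() the message
        return self.args[0]


class DegenerateGeometryError(GpcrActivityError, ValueError):
    """Geometry is degenerate (zero-length vector in an angle computation)."""


class InsufficientAnchorsError(GpcrActivityError, ValueError):
    """Fewer than three shared C-alpha anchors available for superposition."""


class DegenerateDataError(GpcrActivityError, ValueError):
    """Training data cannot support the requested task (e.g. one class)."""


class SchemaMismatchError(GpcrActivityError, ValueError):
    """A feature vector does not match the schema a model was trained on."""


class EmptyResultError(GpcrActivityError, ValueError):
    """An operation produced no usable output (no scorable frames,
    empty histogram input)."""


class NoPathError(GpcrActivityError, RuntimeError):
    """No finite-barrier path exists between two landscape cells."""


class InsufficientStatesError(GpcrActivityError, ValueError):
    """Fewer than two density peaks: no transition pathway can be built."""


class UndefinedActivityError(GpcrActivityError, ValueError):
    """No occupied cells in the requested neighborhood: basin activity
    is undefined."""


class StabilityError(GpcrActivityError, RuntimeError):
    """Numerical integration diverged (time step too large)."""
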