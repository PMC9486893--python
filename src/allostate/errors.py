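"""Exception hierarchy shared across the package."""


class AllostateError(Exception):
    """Base class for all package-specific errors."""


class InputError(AllostateError):
    """Invalid user input (bad sequence, unknown format, bad position...)."""


class ConfigError(AllostateError):
    """Inconsistent configuration (thresholds, fractions, grids...)."""


class MissingAtomError(AllostateError):
    """A requested atom does not exist in the addressed residue/frame."""


class AbsentPositionError(AllostateError):
    """A normalized position is deleted in the query chain."""


class DegenerateGeometryError(AllostateError):
    """Geometry too degenerate to define the requested quantity."""


class UnsupportedResidueError(AllostateError):
    """The residue type cannot support the requested analysis."""


class FitError(AllostateError):
    """Nonlinear fit failed to converge after all restarts."""
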