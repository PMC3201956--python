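"""Exception hierarchy shared across the package."""


class AllositeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AllositeError, ValueError):
    """A parameter or input value violates its contract."""


class MalformedStructureError(AllositeError):
    """A structure file parsed, but does not look like a protein (e.g. no C-alpha atoms)."""


class FitError(AllositeError):
    """Rigid-body superposition failed (too few or degenerate fit points)."""


class CoreFailureError(AllositeError):
    """Invariant-core search eliminated too many positions to continue."""


class InsufficientDataError(AllositeError):
    """Not enough observations for the requested analysis (e.g. PCA with one conformer)."""
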