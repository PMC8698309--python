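"""Exception hierarchy for caflex."""


class CaflexError(Exception):
    """Base class for all caflex errors."""


class PDBParseError(CaflexError):
    """Input text is not parseable PDB (e.g. no ATOM records)."""


class ShapeError(CaflexError):
    """Array/atom-count mismatch (ragged trajectory frames, size mismatch)."""


class ChainNotFoundError(CaflexError, LookupError):
    """Requested chain is absent from the structure."""


class IntegrityError(CaflexError):
    """Structure violates assumptions (duplicate CA, insertion codes)."""


class AlignmentError(CaflexError):
    """Malformed alignment or sequence/structure mismatch."""


class DegenerateFitError(CaflexError):
    """Too few or collinear points for a rigid-body fit."""


class CoreError(CaflexError):
    """Invariant-core search cannot proceed (too few usable columns)."""


class SampleError(CaflexError):
    """Too few samples/frames for the requested statistic."""


class GeometryError(CaflexError):
    """Degenerate geometry (coincident or collinear atoms)."""


class DisconnectedNetworkError(CaflexError):
    """Elastic network has more than six near-zero modes.

    Caused by a disconnected spring network or degenerate (collinear)
    geometry; the message reports the number of connected components.
    """

    def __init__(self, message: str, n_components: int = 1):
        super().__init__(message)
        self.n_components = n_components


class ParameterError(CaflexError, ValueError):
    """Invalid user parameter (k, thresholds, region ranges)."""
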