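"""Exception types shared across the package."""


class TetramethError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TetramethError, ValueError):
    """A simulation or model parameter is outside its valid range."""


class DataError(TetramethError, ValueError):
    """Input data violate a precondition (empty, degenerate, mismatched)."""


class NoInformativeSites(DataError):
    """A bisulfite molecule has no informative CpG site."""


class TetraploidTakeover(TetramethError):
    """The tetraploid subpopulation outgrows the diploid one, so no interior
    equilibrium fraction exists."""
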