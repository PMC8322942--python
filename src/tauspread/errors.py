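"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ``DataError`` -> 2, ``NumericalError`` -> 3,
usage problems -> 1.
"""


class TauspreadError(Exception):
    """Base class for all package-specific errors."""


class DataError(TauspreadError):
    """Malformed, inconsistent or missing input data."""


class DegenerateMixtureError(DataError):
    """Two-component Gaussian mixture fit collapsed; a fixed positivity
    threshold override should be supplied instead."""


class NumericalError(TauspreadError):
    """Integration or sampling failure (non-finite state, solver breakdown)."""
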