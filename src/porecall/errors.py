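"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the command-line layer: validation problems
(bad configuration, malformed tables) exit 2; statistically insufficient
input (too few events for a fit, a class below its minimum) exits 3;
anything unexpected exits 1.
"""


class PorecallError(Exception):
    """Base class for all package errors."""


class ValidationError(PorecallError):
    """Invalid configuration, parameter or file content."""


class FormatError(ValidationError):
    """Malformed input table or trace file."""


class InsufficientDataError(PorecallError):
    """Not enough events/samples for the requested statistic."""
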