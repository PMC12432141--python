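"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (validation 2, format 3, I/O 4) so that
batch callers can distinguish bad parameters from bad files.
"""


class CaescreenError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CaescreenError):
    """A parameter, shape or label violates a documented precondition."""


class FormatError(CaescreenError):
    """An input file exists but is not in the expected format."""
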