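"""Exception types shared across probfuse modules."""


class ProbfuseError(Exception):
    """Base class for all errors raised by probfuse."""


class ValidationError(ProbfuseError, ValueError):
    """An in-memory object violates one of its invariants."""


class FormatError(ProbfuseError, ValueError):
    """An input file cannot be parsed in the expected dialect."""
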