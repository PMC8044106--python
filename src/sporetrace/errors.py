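"""Exception hierarchy shared across the package."""


class SporetraceError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SporetraceError, ValueError):
    """Input violates a documented precondition."""


class BarcodeGenerationError(SporetraceError, RuntimeError):
    """Rejection sampling could not satisfy the requested barcode constraints."""


class FormatError(SporetraceError, ValueError):
    """A file or stream is malformed (e.g. desynchronized FASTQ mates)."""


class ReconciliationError(SporetraceError, KeyError):
    """A sample present in the count table is missing from the sample sheet."""


class UndefinedFitnessError(SporetraceError, ValueError):
    """A CFU count makes the fitness formula undefined; names the field."""


class InsufficientReplicatesError(SporetraceError, ValueError):
    """Too few replicate values for the requested inference."""


class InvalidDesignError(SporetraceError, ValueError):
    """A statistical design is degenerate (e.g. singleton group)."""


class DegenerateInputError(SporetraceError, ValueError):
    """Input has no usable variation (e.g. all-constant matrix)."""


class OutOfRangeError(SporetraceError, ValueError):
    """Requested point lies outside the data range."""
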