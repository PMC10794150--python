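"""Exception hierarchy for trnadisplay."""


class TrnaDisplayError(Exception):
    """Base class for all package-specific errors."""


class InvalidSchemeError(TrnaDisplayError):
    """A degenerate codon scheme contains a non-IUPAC DNA symbol."""


class UntranslatableCodonError(TrnaDisplayError):
    """A codon contains an ambiguous base and cannot be translated."""


class DesignError(TrnaDisplayError):
    """A library design violates its structural invariants."""


class SampleSheetError(TrnaDisplayError):
    """A sample sheet or sample specification is inconsistent."""


class FastqFormatError(TrnaDisplayError):
    """A FASTQ record is malformed; the message names the record index."""


class EmptySampleError(TrnaDisplayError):
    """A count table sample has zero total counts."""


class EmptyResultError(TrnaDisplayError):
    """No variant survived the positive-replicate intersection."""


class SimulationError(TrnaDisplayError):
    """Simulation parameters are out of range or degenerate."""


class InvalidCurveError(TrnaDisplayError):
    """A qPCR standard curve cannot be fitted from the given points."""


class DegenerateFitError(TrnaDisplayError):
    """A regression cannot be fitted (e.g. constant predictor)."""


class ConfigError(TrnaDisplayError):
    """A configuration file is missing required keys or has bad values."""
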