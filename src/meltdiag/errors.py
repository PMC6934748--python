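"""Exception hierarchy for meltdiag.

Each error class maps to one failure mode of the pipeline so callers (and the
CLI) can distinguish bad input files from infeasible designs or degenerate
numerics.
"""


class MeltdiagError(Exception):
    """Base class for all meltdiag errors."""


class InputError(MeltdiagError):
    """Missing/empty input, unknown species label, malformed table."""


class AlignmentError(InputError):
    """Sequences of unequal length where an alignment is required."""


class AlphabetError(InputError):
    """Character outside the accepted A/C/G/T/N/- alphabet."""


class ConfigError(MeltdiagError):
    """Invalid configuration value (genetic code id, thresholds, conditions)."""


class DesignError(MeltdiagError):
    """Assay design is infeasible (e.g. no fixed diagnostic site)."""


class AmbiguityError(DesignError):
    """In-silico PCR found more than one product."""

    def __init__(self, message, loci=None):
        super().__init__(message)
        self.loci = list(loci) if loci is not None else []


class NormalizationError(MeltdiagError):
    """Degenerate baseline window during melt-curve normalization."""


class NumericError(MeltdiagError):
    """Pathological thermodynamic input (division by ~0)."""


class SpecError(MeltdiagError):
    """Infeasible synthetic-data specification."""
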