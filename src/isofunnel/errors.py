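"""Exception hierarchy shared across the pipeline stages."""


class IsofunnelError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(IsofunnelError):
    """A simulation or pipeline configuration violates its invariants."""


class DataError(IsofunnelError):
    """An input table is malformed or inconsistent (missing lengths,
    zero library size, identifier mismatches, ...)."""


class GenerationError(IsofunnelError):
    """The synthetic-data generator cannot honour the requested design,
    e.g. a switch planted in a single-isoform gene."""


class ClassificationError(IsofunnelError):
    """Transfrag classification received incomparable exon chains
    (strand mismatch)."""


class ComputationError(IsofunnelError):
    """A closed-form assay computation received a degenerate input."""
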