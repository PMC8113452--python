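"""Exception hierarchy shared across the pipeline.

Each stage raises a subclass of :class:`GdpRiskError`; the command-line layer
maps these onto exit codes (usage = 2, data/validation = 3, numeric = 4).
"""


class GdpRiskError(Exception):
    """Base class for all pipeline errors."""


class UsageError(GdpRiskError):
    """Bad configuration, unknown schema, or invalid parameter domain."""


class InputError(GdpRiskError):
    """An input file is missing or unreadable."""


class FormatError(GdpRiskError):
    """A file was readable but malformed (e.g. missing dosage tag)."""


class SchemaError(GdpRiskError):
    """A delimited table lacks required columns."""


class ValidationError(GdpRiskError):
    """Record-level constraint violation (e.g. ancestry rows not summing to 1)."""


class JoinError(GdpRiskError):
    """Genotype and covariate sample sets do not overlap."""


class DesignError(GdpRiskError):
    """A regression design matrix is unusable (constant or collinear column)."""


class NumericError(GdpRiskError):
    """A fit produced a non-finite objective or failed to converge fatally."""


class AccrualError(GdpRiskError):
    """Retrospective sampling could not accrue the requested cases/controls."""
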