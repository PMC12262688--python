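"""Exception hierarchy for the EV-miRNA array pipeline.

All pipeline errors derive from :class:`EvMirnaError` so callers can catch
one base class; subclasses distinguish contract violations that a user can
fix (file format, sample sheet pairing) from internal consistency failures.
"""


class EvMirnaError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EvMirnaError):
    """An input table is malformed (missing column, unknown label, bad value)."""


class DuplicateRecordError(FormatError):
    """The same (sample, card, assay) well appears more than once."""


class PairingError(FormatError):
    """A pair id maps to more than one treated or vehicle-control sample."""


class OrphanSampleError(EvMirnaError):
    """A well references a sample absent from the sample sheet."""


class UndefinedRateError(EvMirnaError):
    """A detection rate was requested for an empty sample group."""


class NormalizationError(EvMirnaError):
    """No assay satisfies the endogenous-normalizer criteria."""


class InternalConsistencyError(EvMirnaError):
    """A post-condition the pipeline guarantees was violated (a bug)."""


class UndefinedTestError(EvMirnaError):
    """A statistical test cannot be computed on the given data."""


class ContractError(EvMirnaError):
    """An operation was called with arguments violating its contract."""
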