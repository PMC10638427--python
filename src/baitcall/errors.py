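"""Exception hierarchy for baitcall.

All errors raised on invalid user input derive from :class:`BaitcallError`
so callers can catch one base class; the subclasses mirror the kind of
input that was wrong (experimental design, data values, file format,
statistics preconditions).
"""


class BaitcallError(Exception):
    """Base class for all baitcall errors."""


class DesignError(BaitcallError):
    """The sample design is inconsistent (duplicate runs, wrong replicate
    counts, unknown roles or conditions, missing control groups)."""


class DataError(BaitcallError):
    """Protein-list content is invalid (negative intensities, duplicate
    accessions)."""


class FormatError(BaitcallError):
    """A file does not have the expected layout (e.g. no accession column)."""


class StatsError(BaitcallError):
    """A statistical operation was called on insufficient data."""


class ParameterError(BaitcallError):
    """Simulation parameters are inconsistent."""
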