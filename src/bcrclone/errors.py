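"""Exception hierarchy for bcrclone."""


class BcrcloneError(Exception):
    """Base class for all package errors."""


class SchemaError(BcrcloneError):
    """A required column or field is missing from an input table."""


class ConfigurationError(BcrcloneError):
    """An invalid configuration value or inconsistent reference set."""


class GermlineReferenceError(BcrcloneError):
    """A V/J call does not resolve to a known germline segment."""


class AlignmentError(BcrcloneError):
    """Sequence and germline alignments are incompatible (e.g. length mismatch)."""


class SimulationError(BcrcloneError):
    """The simulator could not satisfy its constraints (e.g. no in-frame junction)."""
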