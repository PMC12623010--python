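"""Exception hierarchy for the famrisk pipeline."""


class FamriskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FamriskError, ValueError):
    """A parameter or config field is invalid; the message names the field."""


class PedigreeError(FamriskError, ValueError):
    """A genealogy violates a structural invariant (cycles, sex of parents, ...)."""


class ParseError(FamriskError, ValueError):
    """A file row could not be parsed; the message carries the line number."""


class ReferentialIntegrityError(FamriskError, ValueError):
    """A row references a person id that does not exist."""


class PersonLookupError(FamriskError, KeyError):
    """An operation was asked about an unknown person id."""


class DegenerateFitError(FamriskError, ValueError):
    """The outcome has a single class; no odds ratio is estimable."""


class SeparationError(FamriskError, ValueError):
    """Quasi-complete separation: a coefficient diverged during IRLS."""


class UndefinedORError(FamriskError, ValueError):
    """A 2x2 table has an empty margin; the odds ratio is undefined."""
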