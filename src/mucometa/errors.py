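"""Exception hierarchy for mucometa.

All package-specific failures derive from :class:`MucometaError` so callers
can distinguish "this input violates a documented precondition" from
programming errors.
"""


class MucometaError(Exception):
    """Base class for all mucometa errors."""


class InvalidParameterError(MucometaError, ValueError):
    """A parameter violates its documented invariant."""


class InputIntegrityError(MucometaError, ValueError):
    """Input data violates an integrity constraint (e.g. duplicate gene ids)."""


class DegenerateDataError(MucometaError, ValueError):
    """Data is too degenerate for the requested computation
    (zero variance, too few values, empty groups, single cluster...)."""


class CollinearityError(MucometaError, ValueError):
    """The two community curves are indistinguishable; the mixture design is singular."""


class MapParseError(MucometaError, ValueError):
    """A mapping file (KO->pathway, KO->CAZy) is malformed."""
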