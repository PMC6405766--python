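"""Exception hierarchy.

Every error raised on a user-facing code path derives from
:class:`FibrilkitError` so callers can catch one type.
"""


class FibrilkitError(Exception):
    """Base class for all package errors."""


class FormatError(FibrilkitError):
    """A coordinate file could not be parsed or written."""


class EmptyModelError(FibrilkitError):
    """A structure contained zero atoms."""


class EmptySelectionError(FibrilkitError):
    """A selection matched nothing."""


class InsufficientSubunitsError(FibrilkitError):
    """Too few chains to define a fibril axis."""


class NonHelicalModelError(FibrilkitError):
    """Consecutive chains are not conformationally identical copies."""


class MissingAtomError(FibrilkitError):
    """A named atom required by a measurement is absent."""


class EmptyStatisticError(FibrilkitError):
    """No eligible residues for a summary statistic."""


class BuildError(FibrilkitError):
    """The synthetic backbone builder produced an unphysical model."""
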