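"""Exception hierarchy for iabkit.

Every operational failure mode raises a subclass of :class:`IabkitError` so
callers (and the CLI) can distinguish bad input from bugs.
"""


class IabkitError(Exception):
    """Base class for all iabkit errors."""


# --- numbering ---------------------------------------------------------------

class NoReferenceMatch(IabkitError):
    """Best alignment to every bundled reference fell below the identity
    threshold — the input is probably not an antibody V-domain."""


class AmbiguousNumbering(IabkitError):
    """Two references tie in alignment score but disagree on CDR lengths."""


class UnknownPosition(IabkitError):
    """A Kabat label was requested that the numbered domain does not carry."""


# --- grafting ----------------------------------------------------------------

class UnresolvedPosition(IabkitError):
    """A graft-set label does not resolve in the numbered acceptor domain."""


class EmptyInput(IabkitError):
    """An aggregate operation received an empty collection."""


class MissingPosition(IabkitError):
    """A positional frequency table lacks a queried Kabat label."""


class UnknownLabel(IabkitError):
    """A logo was requested for a label absent from the frequency table."""


class UnknownFormat(IabkitError):
    """Unrecognized antibody format name."""


# --- self-association --------------------------------------------------------

class NonPositiveInput(IabkitError):
    """A quantity that must be strictly positive was zero or negative."""


class NonConvergence(IabkitError):
    """The monomer-dimer fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# --- alanine scanning / structures -------------------------------------------

class MissingWT(IabkitError):
    """No wild-type record in a binding table."""


class AllExcluded(IabkitError):
    """Every record fell below the capture threshold."""


class NoCoordinates(IabkitError):
    """No flagged position could be resolved to a structure coordinate."""


class NoCAAtoms(IabkitError):
    """The structure file contains no alpha-carbon atoms."""


class UnknownChain(IabkitError):
    """Requested chain(s) absent from the structure."""


# --- tracking ----------------------------------------------------------------

class NoDisplacements(IabkitError):
    """No track long enough to yield a displacement pair."""


class InsufficientLags(IabkitError):
    """MSD curve has fewer lags than requested for the linear fit."""


class NoIntensities(IabkitError):
    """TrackSet carries no intensity data."""


# --- io ----------------------------------------------------------------------

class MalformedRecord(IabkitError):
    """A sequence record failed validation; carries the offending line."""
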