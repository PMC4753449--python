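"""Exception types shared across the package."""


class RingflexError(Exception):
    """Base class for all package errors."""


class ParseError(RingflexError):
    """A coordinate or scattering file could not be parsed."""


class EmptySelectionError(RingflexError):
    """A residue/chain selection matched no atoms."""


class SuperpositionError(RingflexError):
    """Too few or degenerate common beads for rigid-body superposition."""


class DegenerateTransitionError(RingflexError):
    """Two conformers coincide after superposition; no transition vector."""


class DisconnectedNetworkError(RingflexError):
    """The elastic network has more than one connected component."""
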