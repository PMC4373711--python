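"""Exception hierarchy.

All user-facing failures derive from :class:`StarpotError` so the CLI can map
them to a data-error exit code.
"""


class StarpotError(Exception):
    """Base class for all starpot errors."""


class InputError(StarpotError):
    """Malformed or unreadable input (file, sequence, distance, manifest)."""


class EmptySelectionError(StarpotError):
    """A model/chain selection left no atoms to work with."""


class IncompatibilityError(StarpotError):
    """Objects built against different registries or binnings were combined."""


class DegenerateInputError(StarpotError):
    """Statistically degenerate input, e.g. a constant sequence in a correlation."""
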