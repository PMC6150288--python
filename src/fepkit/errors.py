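"""Exception hierarchy.

ValidationError maps to CLI exit code 2, ComputationError to 3.
"""


class FepkitError(Exception):
    """Base class for all fepkit errors."""


class ValidationError(FepkitError):
    """Invalid input: malformed files, broken invariants, bad parameters."""


class ComputationError(FepkitError):
    """A computation could not be completed (e.g. no BAR bracket found)."""
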