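"""Exception hierarchy for the octal package."""


class OctalError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(OctalError):
    """Malformed Newick input (message carries the underlying position info)."""


class TreeValidationError(OctalError):
    """A tree violates a structural invariant (duplicate labels, not binary, ...)."""


class LeafSetError(OctalError):
    """Leaf sets of two trees (or a tree and a taxon subset) do not line up."""

    def __init__(self, message: str, only_in_a=(), only_in_b=()):
        super().__init__(message)
        self.only_in_a = frozenset(only_in_a)
        self.only_in_b = frozenset(only_in_b)


class NotBinaryError(TreeValidationError):
    """An algorithm that requires binary trees was given a multifurcating one."""


class OracleCapError(OctalError):
    """The brute-force completion enumeration would exceed its instance cap."""
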