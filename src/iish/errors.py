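"""Typed errors raised by validation throughout the package."""


class IishError(Exception):
    """Base class for all package errors."""


class GeometryError(IishError):
    """A mask or volume does not live on the expected voxel lattice."""


class SchemaError(IishError):
    """A tabular input is missing columns or contains unknown labels."""


class ValidationError(IishError):
    """A value violates a domain invariant (range, emptiness, finiteness)."""


class ProtocolError(IishError):
    """A statistical protocol precondition is not met (e.g. class too small)."""
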