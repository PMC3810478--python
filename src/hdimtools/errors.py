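"""Exception types shared across the package."""


class HdimError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HdimError, ValueError):
    """A scalar argument is outside its physically meaningful domain."""


class InvalidPartitionError(HdimError, ValueError):
    """Channel edges are not strictly increasing or fall outside the domain."""


class DegenerateSpectrumError(HdimError, ValueError):
    """An emission spectrum places essentially no mass inside the detection band."""


class IncompatibleEndmembersError(HdimError, ValueError):
    """Endmember signatures were built on different detection grids."""


class SingularModelError(HdimError, ValueError):
    """The Fisher information matrix is singular (degenerate endmembers)."""


class ConfigError(HdimError, ValueError):
    """A run configuration failed schema validation."""
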