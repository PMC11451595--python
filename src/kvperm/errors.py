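"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, InputError (and its
subclasses) -> 3, InternalConsistencyError -> 4.
"""


class KvpermError(Exception):
    """Base class for all package errors."""


class ConfigError(KvpermError):
    """Invalid configuration or parameter value."""


class InputError(KvpermError):
    """Invalid or inconsistent input data."""


class StructuralInputError(InputError):
    """A scaffold is missing atoms required by a named role."""


class GeometryError(InputError):
    """Scaffold coordinates do not define a usable pore geometry."""


class InternalConsistencyError(KvpermError):
    """An invariant of the stochastic simulation was violated; fail loudly."""
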