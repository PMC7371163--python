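"""Exception hierarchy for memlens.

All package-specific failures derive from :class:`MemlensError` so callers
can catch everything from one place while tests can assert on the precise
failure mode.
"""


class MemlensError(Exception):
    """Base class for all memlens errors."""


class FormatError(MemlensError):
    """A structure or trajectory file could not be parsed."""


class ClassificationError(MemlensError):
    """A residue name could not be mapped to a molecular species."""


class ConsistencyError(MemlensError):
    """Topology and trajectory disagree (e.g. atom counts differ)."""


class ConfigurationError(MemlensError):
    """An analysis was requested with incompatible settings
    (e.g. periodic contacts without box information)."""


class UnsupportedBoxError(ConfigurationError):
    """The unit cell is not orthorhombic."""


class MappingError(MemlensError):
    """A binding-site map could not be constructed or applied."""


class NoContactsError(MemlensError):
    """A ratio was requested over a window with zero qualifying contacts."""


class GenerationError(MemlensError):
    """A synthetic system could not be realised (infeasible geometry
    or an over-subscribed contact schedule)."""
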