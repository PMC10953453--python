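"""Exception hierarchy for the memtop pipeline."""


class MemtopError(Exception):
    """Base class for all memtop errors."""


class InvalidResidueError(MemtopError):
    """A sequence letter outside the 20 standard amino acids."""


class InvalidChargeError(MemtopError):
    """Charge state must be a positive integer."""


class InvalidInputError(MemtopError):
    """Numerically invalid input (e.g. m/z at or below the proton mass)."""


class InconsistentMassError(MemtopError):
    """Measured mass exceeds the theoretical chain mass beyond tolerance."""


class ConfigError(MemtopError):
    """Invalid pipeline or simulation configuration."""


class TopologyError(MemtopError):
    """Topology table fails validation (overlap, gap, bad kind)."""


class InsufficientMembersError(MemtopError):
    """A charge series needs at least two members for a mass estimate."""


class AssignmentError(MemtopError):
    """An assignment references a site outside the sequence."""
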