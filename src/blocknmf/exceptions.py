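"""Exception hierarchy.

All package errors derive from :class:`BlockNMFError` so callers can catch one
base class; the subclasses distinguish bad file contents, invalid numeric
domains, shape mismatches, infeasible configurations, and collective-sync
failures.
"""


class BlockNMFError(Exception):
    """Base class for all blocknmf errors."""


class FormatError(BlockNMFError):
    """A file's structure is wrong: ragged rows, bad size, unparsable cell."""


class DomainError(BlockNMFError, ValueError):
    """Values outside the model's domain (negative, NaN, infinite)."""


class DimensionError(BlockNMFError, ValueError):
    """Matrix shapes are not conformable for the requested operation."""


class ConfigError(BlockNMFError, ValueError):
    """An invalid run configuration (rank, budget, worker count, ...)."""


class StateError(BlockNMFError):
    """Inconsistent convergence-tracking state across tests."""


class SyncError(BlockNMFError):
    """A collective synchronization step received inconsistent contributions."""
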