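"""Exception hierarchy shared across the package."""


class MesotypesError(Exception):
    """Base class for all package errors."""


class GraphParseError(MesotypesError, ValueError):
    """A graph file could not be parsed; message names the offending line."""


class CoverageError(MesotypesError, ValueError):
    """A partition or attribute table does not cover the graph's node set."""


class ConflictError(MesotypesError, ValueError):
    """Contradictory rows in an input table (e.g. a node assigned twice)."""


class UsageError(MesotypesError, ValueError):
    """An operation was invoked with arguments that violate its contract."""
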