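"""Exception hierarchy for fifoflow.

All library errors derive from :class:`FifoflowError` so callers (and the
CLI) can catch one type.  Usage-level problems (bad option tokens, duplicate
names, unbound inputs) raise :class:`DefinitionError` subtypes; runtime
problems raise :class:`ExecutionError` subtypes.
"""

from __future__ import annotations


class FifoflowError(Exception):
    """Base class for all fifoflow errors."""


class DefinitionError(FifoflowError):
    """A program definition violates a structural rule."""


class MalformedOptionError(DefinitionError):
    """An option token does not start with '-'."""


class DuplicateNameError(DefinitionError):
    """A process, option or FIFO name collides with an existing one."""


class DirectionMismatchError(DefinitionError):
    """A connection pairs two ports of incompatible direction."""


class UnknownProcessError(DefinitionError):
    """A connection references a process that is not registered."""


class UnknownPortError(DefinitionError):
    """A connection references an option token not declared on the process."""


class PortAlreadyBoundError(DefinitionError):
    """An input port would be bound by more than one channel (single-producer rule)."""


class UnboundInputError(DefinitionError):
    """A required input port is left unbound after resolution."""


class CycleError(DefinitionError):
    """A cycle was found where only a DAG is allowed (job-step subgraph)."""


class MalformedArgsError(DefinitionError):
    """An option token is present on the command line without a value."""


class UnknownOptionError(DefinitionError):
    """A command-line token does not match any documented program option."""


class ExecutionError(FifoflowError):
    """A runtime failure while executing a resolved network."""


class NotAnOutputTreeError(ExecutionError):
    """The given directory is not a program output directory."""


class BackendError(ExecutionError):
    """A batch backend rejected or lost a submission."""


class SchedulerError(ExecutionError):
    """The selected scheduling mode cannot run the given network."""
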