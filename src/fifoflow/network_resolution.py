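"""Compile a :class:`ProgramSpec` into a :class:`ResolvedNetwork`.

Resolution runs every process's connection rule exactly once (eager lists
are taken as-is; generator rules are drained, one directive list per array
task), creates channels, binds command-line values, classifies cyclicity
and derives the job-step dependency graph.

Channels are symbolic here: stream channels carry a FIFO basename, file
channels point at the producer's output-file binding.  Actual filesystem
paths are filled in at materialization time (see :mod:`.channel_layer`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .errors import (
    CycleError,
    DefinitionError,
    DirectionMismatchError,
    DuplicateNameError,
    PortAlreadyBoundError,
    UnboundInputError,
    UnknownOptionError,
    UnknownProcessError,
)
from .program_model import (
    FBP_PROCESS,
    INPUT,
    JOB_STEP,
    NOT_FOUND,
    OUTPUT,
    CmdlineOpt,
    Directive,
    FifoOpt,
    FromProcessOut,
    OutFile,
    ProgramSpec,
    ValueOpt,
    fifo_basename,
    read_opt_value,
)

__all__ = [
    "Endpoint",
    "Channel",
    "Binding",
    "ResolvedNetwork",
    "ConnectContext",
    "resolve",
    "build_dependency_graph",
    "export_graph",
]

PROCESS_PORT = "process_port"
EXTERNAL = "external"


@dataclass(frozen=True)
class Endpoint:
    kind: str  # process_port | external
    process: str = ""
    option_token: str = ""
    external_name: str = ""

    @classmethod
    def port(cls, process: str, token: str) -> "Endpoint":
        return cls(kind=PROCESS_PORT, process=process, option_token=token)

    @classmethod
    def external(cls, name: str) -> "Endpoint":
        return cls(kind=EXTERNAL, external_name=name)


@dataclass(frozen=True)
class Channel:
    """A resolved connection between two endpoints."""

    producer: Endpoint
    consumer: Endpoint
    medium: str  # stream | file | value
    fifo_basename: str = ""  # stream channels only


@dataclass(frozen=True)
class Binding:
    """One resolved option for a process task.

    ``source`` is one of:

    * ``literal`` — *value* is the option value verbatim;
    * ``stream`` — the option resolves to the FIFO path of channel *channel*;
    * ``file_in`` — the option resolves to the producer-side output file of
      channel *channel* (mapped by task index);
    * ``file_out`` — the option resolves to ``<own dir>/<value>`` with
      ``{task}`` substituted.
    """

    token: str
    source: str
    value: str = ""
    channel: int = -1


class ConnectContext:
    """What a generator-style connection rule can see at resolve time."""

    def __init__(self, program: ProgramSpec, process: str, cmdline: Sequence[str]):
        self.program = program
        self.process = process
        self._cmdline = list(cmdline)

    def cmdline_value(self, token: str, default: str | None = None) -> str | None:
        value = read_opt_value(self._cmdline, token)
        if value is NOT_FOUND:
            return default
        return value


@dataclass
class ResolvedNetwork:
    """The compiled program: processes, channels, per-task option lists."""

    program: ProgramSpec
    channels: list[Channel]
    bindings: dict[str, list[list[Binding]]]  # process -> per-task ordered bindings
    task_counts: dict[str, int]
    cyclic: bool
    dependency_graph: nx.DiGraph
    warnings: list[str] = field(default_factory=list)

    # -- argv construction ---------------------------------------------------

    def argv(self, process: str, task: int, tree) -> list[str]:
        """Flatten the resolved option list for one task into argv tokens.

        *tree* must provide ``fifo_path(basename)`` and
        ``process_dir(name)`` (see :class:`fifoflow.channel_layer.OutputTree`).
        """
        out: list[str] = []
        for b in self.bindings[process][task]:
            out.append(b.token)
            out.append(self.binding_value(process, task, b, tree))
        return out

    def binding_value(self, process: str, task: int, b: Binding, tree) -> str:
        if b.source == "literal":
            return b.value
        if b.source == "stream":
            return str(tree.fifo_path(self.channels[b.channel].fifo_basename))
        if b.source == "file_out":
            return str(tree.process_dir(process) / b.value.format(task=task))
        if b.source == "file_in":
            ch = self.channels[b.channel]
            prod = ch.producer.process
            ptask = self._map_task(process, prod, task)
            pb = self._find_binding(prod, ptask, ch.producer.option_token)
            return self.binding_value(prod, ptask, pb, tree)
        raise DefinitionError(f"unknown binding source {b.source!r}")

    def _map_task(self, consumer: str, producer: str, task: int) -> int:
        p, c = self.task_counts[producer], self.task_counts[consumer]
        if p == c:
            return task
        if p == 1:
            return 0
        raise DefinitionError(
            f"cannot map task {task} of {consumer} (x{c}) onto producer "
            f"{producer} (x{p}); array sizes must match or producer be scalar"
        )

    def _find_binding(self, process: str, task: int, token: str) -> Binding:
        for b in self.bindings[process][task]:
            if b.token == token:
                return b
        raise UnboundInputError(
            f"producer {process} has no binding for output {token!r}"
        )

    # -- structure queries ---------------------------------------------------

    def stream_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.medium == "stream"]

    def producers_of(self, process: str) -> list[str]:
        """Names of processes whose output this process consumes (any medium)."""
        out = []
        for ch in self.channels:
            if (
                ch.consumer.kind == PROCESS_PORT
                and ch.consumer.process == process
                and ch.producer.kind == PROCESS_PORT
            ):
                if ch.producer.process not in out:
                    out.append(ch.producer.process)
        return out

    def job_steps(self) -> list[str]:
        return [
            s.name
            for s in self.program.processes
            if s.effective_exec_class == JOB_STEP
        ]

    def fbp_processes(self) -> list[str]:
        return [
            s.name
            for s in self.program.processes
            if s.effective_exec_class == FBP_PROCESS
        ]


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------


class _Resolver:
    def __init__(self, program: ProgramSpec, cmdline: Sequence[str]):
        self.program = program
        self.cmdline = list(cmdline)
        self.channels: list[Channel] = []
        self.bindings: dict[str, list[list[Binding]]] = {}
        self.task_counts: dict[str, int] = {}
        self.warnings: list[str] = []
        self._fifo_names: set[str] = set()
        self._bound_inputs: set[tuple[str, str]] = set()  # (process, token)
        self._bound_outputs: set[tuple[str, str]] = set()
        self._consumed_cmdline: set[tuple[str, str]] = set()
        # producer-side bindings created on behalf of consumers, keyed by
        # (process, token); appended after the process's own directives
        self._auto: dict[str, dict[str, Binding]] = {}

    # -- command line --------------------------------------------------------

    def _validate_cmdline(self) -> None:
        documented = self.program.documented_tokens()
        i = 0
        while i < len(self.cmdline):
            tok = self.cmdline[i]
            if not tok.startswith("-"):
                raise UnknownOptionError(
                    f"expected an option token, got {tok!r}"
                )
            if tok not in documented:
                raise UnknownOptionError(
                    f"unknown option {tok!r}; documented options: "
                    + ", ".join(sorted(documented))
                )
            if i + 1 >= len(self.cmdline):
                from .errors import MalformedArgsError

                raise MalformedArgsError(f"option {tok!r} has no value")
            i += 2

    # -- directive handling --------------------------------------------------

    def _task_directives(self) -> dict[str, list[list[Directive]]]:
        out: dict[str, list[list[Directive]]] = {}
        for spec in self.program.processes:
            if spec.connect is not None:
                out[spec.name] = [list(spec.connect) for _ in range(spec.task_count)]
            else:
                ctx = ConnectContext(self.program, spec.name, self.cmdline)
                lists = [list(x) for x in spec.connect_tasks(ctx)]
                if not lists:
                    raise DefinitionError(
                        f"process {spec.name}: connection generator yielded no tasks"
                    )
                if (
                    spec.effective_exec_class == FBP_PROCESS
                    and len(lists) > 1
                ):
                    raise DefinitionError(
                        f"process {spec.name}: task arrays apply to job steps only"
                    )
                out[spec.name] = lists
        return out

    def _check_port(self, process: str, token: str, want_direction: str | None):
        spec = self.program.process(process)
        port = spec.port(token)  # raises UnknownPortError
        if want_direction is not None and port.direction != want_direction:
            raise DirectionMismatchError(
                f"{process}{token} is an {port.direction} port, "
                f"expected {want_direction}"
            )
        return port

    def _claim_input(self, process: str, token: str) -> None:
        key = (process, token)
        if key in self._bound_inputs:
            raise PortAlreadyBoundError(
                f"input {process}{token} bound by more than one channel"
            )
        self._bound_inputs.add(key)

    def _claim_output(self, process: str, token: str) -> None:
        key = (process, token)
        if key in self._bound_outputs:
            raise PortAlreadyBoundError(
                f"output {process}{token} already has a consumer"
            )
        self._bound_outputs.add(key)

    def _claim_fifo(self, basename: str) -> None:
        if basename in self._fifo_names:
            raise DuplicateNameError(f"FIFO basename {basename!r} already in use")
        self._fifo_names.add(basename)

    def _add_stream_channel(self, producer: str, ptoken: str, consumer: Endpoint) -> int:
        basename = fifo_basename(producer, ptoken)
        self._claim_fifo(basename)
        self.channels.append(
            Channel(
                producer=Endpoint.port(producer, ptoken),
                consumer=consumer,
                medium="stream",
                fifo_basename=basename,
            )
        )
        return len(self.channels) - 1

    def run(self) -> ResolvedNetwork:
        self._validate_cmdline()
        task_dirs = self._task_directives()
        for name, lists in task_dirs.items():
            self.task_counts[name] = len(lists)

        # one pass over every process's directives, declaration order
        for spec in self.program.processes:
            name = spec.name
            per_task: list[list[Binding]] = []
            for task, directives in enumerate(task_dirs[name]):
                row: list[Binding] = []
                seen_tokens: set[str] = set()
                for d in directives:
                    if d.token in seen_tokens:
                        raise DuplicateNameError(
                            f"process {name}: option {d.token!r} bound twice"
                        )
                    seen_tokens.add(d.token)
                    row.extend(self._apply(spec, task, d))
                per_task.append(row)
            self.bindings[name] = per_task

        # producer-side bindings created by consumers' connections
        for name, auto in self._auto.items():
            spec = self.program.process(name)
            ordered = [
                auto[p.option_token]
                for p in spec.ports
                if p.option_token in auto
            ]
            for row in self.bindings[name]:
                present = {b.token for b in row}
                row.extend(b for b in ordered if b.token not in present)

        self._check_required_inputs()
        self._check_file_producers()
        self._warn_unconsumed_docs()

        cyclic = self._classify_cycles()
        dep = self._dependency_graph()
        return ResolvedNetwork(
            program=self.program,
            channels=self.channels,
            bindings=self.bindings,
            task_counts=self.task_counts,
            cyclic=cyclic,
            dependency_graph=dep,
            warnings=self.warnings,
        )

    def _apply(self, spec, task: int, d: Directive) -> list[Binding]:
        name = spec.name
        if isinstance(d, CmdlineOpt):
            port = self._check_port(name, d.token, None)
            self._consumed_cmdline.add((name, d.token))
            value = read_opt_value(self.cmdline, d.token)
            if value is NOT_FOUND:
                if port.required:
                    raise UnboundInputError(
                        f"required option {d.token!r} of process {name} "
                        "missing from the command line"
                    )
                return []
            if port.direction == INPUT and task == 0:
                self._claim_input(name, d.token)
            return [Binding(token=d.token, source="literal", value=value)]
        if isinstance(d, ValueOpt):
            port = self._check_port(name, d.token, None)
            if port.direction == INPUT and task == 0:
                self._claim_input(name, d.token)
            return [Binding(token=d.token, source="literal", value=d.value)]
        if isinstance(d, FromProcessOut):
            return [self._apply_from_process_out(spec, task, d)]
        if isinstance(d, FifoOpt):
            return [self._apply_fifo(spec, d)]
        if isinstance(d, OutFile):
            port = self._check_port(name, d.token, OUTPUT)
            if port.payload == "stream":
                raise DefinitionError(
                    f"{name}{d.token}: stream output ports cannot bind to files"
                )
            return [Binding(token=d.token, source="file_out", value=d.filename)]
        raise DefinitionError(f"unknown directive {d!r}")

    def _apply_from_process_out(self, spec, task: int, d: FromProcessOut) -> Binding:
        name = spec.name
        self._check_port(name, d.token, INPUT)
        if not self.program.has_process(d.producer):
            raise UnknownProcessError(
                f"{name}{d.token}: unknown producer process {d.producer!r}"
            )
        pport = self._check_port(d.producer, d.producer_token, OUTPUT)
        if task == 0:
            self._claim_input(name, d.token)
        # a stream output feeds exactly one consumer; file outputs may fan out
        if pport.payload == "stream":
            if task == 0:
                self._claim_output(d.producer, d.producer_token)
                idx = self._add_stream_channel(
                    d.producer, d.producer_token, Endpoint.port(name, d.token)
                )
                self._auto.setdefault(d.producer, {})[d.producer_token] = Binding(
                    token=d.producer_token, source="stream", channel=idx
                )
            else:
                idx = self._find_channel(d.producer, d.producer_token)
            return Binding(token=d.token, source="stream", channel=idx)
        # file (or value payload) channel
        if task == 0:
            self.channels.append(
                Channel(
                    producer=Endpoint.port(d.producer, d.producer_token),
                    consumer=Endpoint.port(name, d.token),
                    medium="file",
                )
            )
        idx = self._find_channel(d.producer, d.producer_token, consumer=name)
        return Binding(token=d.token, source="file_in", channel=idx)

    def _find_channel(self, producer: str, ptoken: str, consumer: str | None = None) -> int:
        for i, ch in enumerate(self.channels):
            if (
                ch.producer.kind == PROCESS_PORT
                and ch.producer.process == producer
                and ch.producer.option_token == ptoken
                and (consumer is None or ch.consumer.process == consumer)
            ):
                return i
        raise DefinitionError(
            f"internal error: channel {producer}{ptoken} not found"
        )

    def _apply_fifo(self, spec, d: FifoOpt) -> Binding:
        name = spec.name
        port = self._check_port(name, d.token, None)
        if port.payload != "stream":
            raise DefinitionError(
                f"{name}{d.token}: FIFO options require a stream payload"
            )
        basename = fifo_basename(name, d.token)
        self._claim_fifo(basename)
        if port.direction == OUTPUT:
            producer = Endpoint.port(name, d.token)
            consumer = Endpoint.external(basename)
            self._claim_output(name, d.token)
        else:
            producer = Endpoint.external(basename)
            consumer = Endpoint.port(name, d.token)
            self._claim_input(name, d.token)
        self.channels.append(
            Channel(
                producer=producer,
                consumer=consumer,
                medium="stream",
                fifo_basename=basename,
            )
        )
        return Binding(token=d.token, source="stream", channel=len(self.channels) - 1)

    # -- validation ----------------------------------------------------------

    def _check_required_inputs(self) -> None:
        for spec in self.program.processes:
            for port in spec.ports:
                if port.direction != INPUT or not port.required:
                    continue
                for task, row in enumerate(self.bindings[spec.name]):
                    if not any(b.token == port.option_token for b in row):
                        raise UnboundInputError(
                            f"required input {spec.name}{port.option_token} "
                            f"is unbound (task {task})"
                        )

    def _check_file_producers(self) -> None:
        for ch in self.channels:
            if ch.medium != "file":
                continue
            prod, tok = ch.producer.process, ch.producer.option_token
            for row in self.bindings[prod]:
                if not any(b.token == tok for b in row):
                    raise UnboundInputError(
                        f"{ch.consumer.process}{ch.consumer.option_token} consumes "
                        f"{prod}{tok}, but {prod} never binds that output"
                    )

    def _warn_unconsumed_docs(self) -> None:
        for (proc, token) in self.program.option_docs:
            if (proc, token) not in self._consumed_cmdline:
                self.warnings.append(
                    f"option {token!r} documented for process {proc} is never "
                    "consumed by its connection rule"
                )

    # -- graph work ----------------------------------------------------------

    def _process_multigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for spec in self.program.processes:
            g.add_node(spec.name)
        for ch in self.channels:
            if ch.producer.kind == PROCESS_PORT and ch.consumer.kind == PROCESS_PORT:
                g.add_edge(ch.producer.process, ch.consumer.process)
        return g

    def _classify_cycles(self) -> bool:
        g = self._process_multigraph()
        cyclic = not nx.is_directed_acyclic_graph(g)
        if cyclic:
            job_steps = set(
                s.name
                for s in self.program.processes
                if s.effective_exec_class == JOB_STEP
            )
            for cycle in nx.simple_cycles(g):
                bad = job_steps.intersection(cycle)
                if bad:
                    raise CycleError(
                        "job steps cannot take part in cycles: "
                        + ", ".join(sorted(bad))
                    )
        # job steps may not consume or produce stream channels
        for ch in self.channels:
            if ch.medium != "stream":
                continue
            for ep in (ch.producer, ch.consumer):
                if ep.kind != PROCESS_PORT:
                    continue
                if self.program.process(ep.process).effective_exec_class == JOB_STEP:
                    raise DefinitionError(
                        f"job step {ep.process} cannot use stream channel "
                        f"{ch.fifo_basename}"
                    )
        return cyclic

    def _dependency_graph(self) -> nx.DiGraph:
        steps = set(
            s.name
            for s in self.program.processes
            if s.effective_exec_class == JOB_STEP
        )
        g = nx.DiGraph()
        for name in self.program.process_names:
            if name in steps:
                g.add_node(name)
        for ch in self.channels:
            if ch.medium != "file":
                continue
            if (
                ch.producer.kind == PROCESS_PORT
                and ch.consumer.kind == PROCESS_PORT
                and ch.producer.process in steps
                and ch.consumer.process in steps
            ):
                g.add_edge(ch.producer.process, ch.consumer.process)
        if g.number_of_nodes() and not nx.is_directed_acyclic_graph(g):
            raise CycleError("dependency graph over job steps contains a cycle")
        return g


def resolve(program: ProgramSpec, cmdline: Sequence[str] = ()) -> ResolvedNetwork:
    """Run every connection rule once and compile the program network."""
    return _Resolver(program, cmdline).run()


def build_dependency_graph(network: ResolvedNetwork) -> nx.DiGraph:
    """DAG over job-step processes; edge u->v iff v consumes a file of u."""
    return network.dependency_graph.copy()


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------

_STYLE = {
    "process_shape": "box",
    "external_shape": "ellipse",
    "stream_style": "solid",
    "file_style": "dashed",
}


def export_graph(network: ResolvedNetwork, kind: str = "process") -> str:
    """Render the network as deterministic DOT text.

    ``process`` draws one node per process and one labeled edge per channel
    (externals as ellipses); ``dependency`` mirrors the job-step DAG.
    """
    lines = [f"digraph {kind} {{"]
    if kind == "process":
        for spec in network.program.processes:
            lines.append(
                f'  "{spec.name}" [shape={_STYLE["process_shape"]}];'
            )
        externals = []
        for ch in network.channels:
            for ep in (ch.producer, ch.consumer):
                if ep.kind == EXTERNAL and ep.external_name not in externals:
                    externals.append(ep.external_name)
        for name in externals:
            lines.append(f'  "{name}" [shape={_STYLE["external_shape"]}];')
        for ch in network.channels:
            src = (
                ch.producer.process
                if ch.producer.kind == PROCESS_PORT
                else ch.producer.external_name
            )
            dst = (
                ch.consumer.process
                if ch.consumer.kind == PROCESS_PORT
                else ch.consumer.external_name
            )
            label_parts = []
            if ch.producer.kind == PROCESS_PORT:
                label_parts.append(ch.producer.option_token)
            if ch.consumer.kind == PROCESS_PORT:
                label_parts.append(ch.consumer.option_token)
            label = " -> ".join(label_parts)
            style = (
                _STYLE["stream_style"]
                if ch.medium == "stream"
                else _STYLE["file_style"]
            )
            lines.append(f'  "{src}" -> "{dst}" [label="{label}", style={style}];')
    elif kind == "dependency":
        g = network.dependency_graph
        order = [n for n in network.program.process_names if n in g]
        for name in order:
            lines.append(f'  "{name}" [shape={_STYLE["process_shape"]}];')
        for u in order:
            for v in sorted(g.successors(u), key=order.index):
                lines.append(f'  "{u}" -> "{v}";')
    else:
        raise DefinitionError(f"unknown graph kind {kind!r}")
    lines.append("}")
    return "\n".join(lines) + "\n"
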