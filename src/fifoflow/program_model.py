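"""Declarative vocabulary for authoring flow programs.

A *program* is an ordered collection of named processes.  Each process has a
body (a shell command, an inline script with a declared interpreter, or a
native Python callable), a set of ports addressed by command-option tokens,
and a *connection rule* describing how its ports are wired to the rest of
the network.

Port direction is purely lexical: tokens starting with ``-out`` or ``--out``
are output ports, everything else is an input port.

Connection rules come in exactly two styles:

* **eager** — a plain list of :class:`Directive` objects, one binding per
  port (the common case, and the only style that serializes to a program
  definition file);
* **generator** — a callable receiving a :class:`ConnectContext` and
  yielding one directive list per array task, which is how a process
  declares at resolve time that it runs as an array.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Sequence, Union

import yaml

from .errors import (
    DefinitionError,
    DuplicateNameError,
    MalformedArgsError,
    MalformedOptionError,
)

__all__ = [
    "NOT_FOUND",
    "INPUT",
    "OUTPUT",
    "FBP_PROCESS",
    "JOB_STEP",
    "classify_port",
    "port_basename",
    "fifo_basename",
    "read_opt_value",
    "PortSpec",
    "BodySpec",
    "Resources",
    "ProcessSpec",
    "ProgramSpec",
    "OptionDoc",
    "CmdlineOpt",
    "ValueOpt",
    "FromProcessOut",
    "FifoOpt",
    "OutFile",
    "Directive",
    "render_help",
    "dump_program",
    "load_program",
]

INPUT = "input"
OUTPUT = "output"

FBP_PROCESS = "fbp_process"
JOB_STEP = "job_step"

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

SCHEMA_VERSION = 1


class _NotFound:
    """Distinguished result for an absent option token (not an exception)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_FOUND"

    def __bool__(self) -> bool:
        return False


NOT_FOUND = _NotFound()


def classify_port(option_token: str) -> str:
    """Return ``"output"`` iff *option_token* starts with ``-out`` or ``--out``.

    Pure and total on well-formed tokens; any other token starting with a
    dash is an input port.
    """
    if not isinstance(option_token, str) or not option_token.startswith("-"):
        raise MalformedOptionError(
            f"option token must start with '-': {option_token!r}"
        )
    if option_token.startswith("--out") or (
        option_token.startswith("-out") and not option_token.startswith("--")
    ):
        return OUTPUT
    return INPUT


def port_basename(option_token: str) -> str:
    """Derive the short port name used in FIFO basenames.

    Lowercase the token, strip leading dashes, then strip one leading
    ``out``/``in`` prefix — unless stripping would leave the name empty
    (so ``-out`` stays ``out`` and ``-in`` stays ``in``, matching names
    like ``counter_out`` and ``stream_echo_in``).
    """
    name = option_token.lower().lstrip("-")
    for prefix in ("out", "in"):
        if name.startswith(prefix) and name != prefix:
            stripped = name[len(prefix) :].lstrip("-_")
            if stripped:
                return stripped
    return name


def fifo_basename(process: str, option_token: str) -> str:
    return f"{process}_{port_basename(option_token)}"


def read_opt_value(args: Sequence[str], option_token: str):
    """Return the value following *option_token* in *args*.

    Returns the **first** occurrence on duplicates.  A missing token yields
    the distinguished :data:`NOT_FOUND` object so callers can branch without
    exception handling.  A token in final position (no value after it) is a
    malformed argument list.
    """
    args = list(args)
    for i, tok in enumerate(args):
        if tok == option_token:
            if i + 1 >= len(args):
                raise MalformedArgsError(
                    f"option {option_token!r} present without a value"
                )
            return args[i + 1]
    return NOT_FOUND


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_PAYLOADS = ("value", "path", "stream")
_VALUE_KINDS = ("int", "string", "path")


@dataclass(frozen=True)
class PortSpec:
    """A named input or output of a process, addressed by its option token."""

    option_token: str
    payload: str = "value"
    required: bool = True
    doc: str = ""
    value_kind: str = "string"

    def __post_init__(self) -> None:
        classify_port(self.option_token)  # validates the token shape
        if self.payload not in _PAYLOADS:
            raise DefinitionError(f"unknown payload {self.payload!r}")
        if self.value_kind not in _VALUE_KINDS:
            raise DefinitionError(f"unknown value_kind {self.value_kind!r}")

    @property
    def direction(self) -> str:
        return classify_port(self.option_token)


@dataclass(frozen=True)
class BodySpec:
    """What a process executes.

    ``command_text`` bodies are run through the shell with the resolved
    option list appended as positional arguments.  ``inline_script`` bodies
    are written to disk byte-exact (no escaping) and run with the declared
    interpreter.  ``native_callable`` bodies call ``fn(args)`` in-process.
    """

    form: str
    text: str = ""
    interpreter: str = ""
    fn: Callable[..., int] | None = None

    def __post_init__(self) -> None:
        if self.form not in ("command_text", "inline_script", "native_callable"):
            raise DefinitionError(f"unknown body form {self.form!r}")
        if self.form == "inline_script" and not self.interpreter:
            raise DefinitionError("inline_script bodies require an interpreter")
        if self.form == "native_callable" and self.fn is None:
            raise DefinitionError("native_callable bodies require fn")

    @classmethod
    def command(cls, text: str) -> "BodySpec":
        return cls(form="command_text", text=text)

    @classmethod
    def script(cls, text: str, interpreter: str) -> "BodySpec":
        return cls(form="inline_script", text=text, interpreter=interpreter)

    @classmethod
    def native(cls, fn: Callable[..., int]) -> "BodySpec":
        return cls(form="native_callable", fn=fn)


@dataclass(frozen=True)
class Resources:
    cpus: int = 1
    mem_mb: int = 256
    time_min: int = 60

    def __post_init__(self) -> None:
        if self.cpus < 1 or self.mem_mb < 1 or self.time_min < 1:
            raise DefinitionError("resources must be positive")


# -- connection directives ---------------------------------------------------


@dataclass(frozen=True)
class CmdlineOpt:
    """Bind the port to the value of a documented command-line option."""

    token: str


@dataclass(frozen=True)
class ValueOpt:
    """Bind the port to a literal value."""

    token: str
    value: str


@dataclass(frozen=True)
class FromProcessOut:
    """Bind this input port to another process's output port (a channel)."""

    token: str
    producer: str
    producer_token: str


@dataclass(frozen=True)
class FifoOpt:
    """Expose the port as a named pipe reachable from outside the program."""

    token: str


@dataclass(frozen=True)
class OutFile:
    """Bind an output port to a file under the process's output directory.

    *filename* may contain ``{task}``, substituted with the 0-based array
    task index at resolution time.
    """

    token: str
    filename: str


Directive = Union[CmdlineOpt, ValueOpt, FromProcessOut, FifoOpt, OutFile]


@dataclass(frozen=True)
class ProcessSpec:
    """A named process template."""

    name: str
    body: BodySpec
    ports: Sequence[PortSpec] = ()
    exec_class: str | None = None  # None -> inferred from port payloads
    resources: Resources = field(default_factory=Resources)
    task_count: int = 1
    connect: Sequence[Directive] | None = None
    connect_tasks: Callable[..., Iterator[Sequence[Directive]]] | None = None

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.name):
            raise DefinitionError(
                f"process name {self.name!r} is not a valid identifier"
            )
        if self.exec_class not in (None, FBP_PROCESS, JOB_STEP):
            raise DefinitionError(f"unknown exec_class {self.exec_class!r}")
        if self.task_count < 1:
            raise DefinitionError("task_count must be positive")
        seen = set()
        for port in self.ports:
            if port.option_token in seen:
                raise DuplicateNameError(
                    f"duplicate port {port.option_token!r} on process {self.name}"
                )
            seen.add(port.option_token)
        eager = self.connect is not None
        lazy = self.connect_tasks is not None
        if eager == lazy:
            raise DefinitionError(
                f"process {self.name}: exactly one of connect (eager list) or "
                "connect_tasks (generator) must be set"
            )
        if self.effective_exec_class == FBP_PROCESS and self.task_count > 1:
            raise DefinitionError(
                f"process {self.name}: task arrays apply to job steps only"
            )

    @property
    def effective_exec_class(self) -> str:
        if self.exec_class is not None:
            return self.exec_class
        if any(p.payload == "stream" for p in self.ports):
            return FBP_PROCESS
        return JOB_STEP

    def port(self, token: str) -> PortSpec:
        for p in self.ports:
            if p.option_token == token:
                return p
        from .errors import UnknownPortError

        raise UnknownPortError(f"process {self.name} has no port {token!r}")

    def has_port(self, token: str) -> bool:
        return any(p.option_token == token for p in self.ports)


@dataclass(frozen=True)
class OptionDoc:
    process: str
    token: str
    value_kind: str
    description: str
    required: bool = True


class ProgramSpec:
    """An ordered, named collection of processes plus option documentation."""

    def __init__(self, module_name: str):
        if not _NAME_RE.match(module_name):
            raise DefinitionError(f"invalid module name {module_name!r}")
        self.module_name = module_name
        self._processes: dict[str, ProcessSpec] = {}
        self._process_module: dict[str, str] = {}
        self._included: set[str] = set()
        self._docs: dict[tuple[str, str], OptionDoc] = {}

    # -- registration -------------------------------------------------------

    def register_process(self, spec: ProcessSpec) -> "ProgramSpec":
        """Append a process, preserving declaration order (the scheduling
        tie-break everywhere ordering matters)."""
        if spec.name in self._processes:
            raise DuplicateNameError(f"process {spec.name!r} already registered")
        self._processes[spec.name] = spec
        self._process_module[spec.name] = self.module_name
        return self

    def document_option(
        self,
        process: str,
        option_token: str,
        value_kind: str = "string",
        description: str = "",
        required: bool = True,
    ) -> "ProgramSpec":
        if process not in self._processes:
            from .errors import UnknownProcessError

            raise UnknownProcessError(f"unknown process {process!r}")
        classify_port(option_token)
        key = (process, option_token)
        if key in self._docs:
            raise DuplicateNameError(
                f"option {option_token!r} already documented for process {process}"
            )
        self._docs[key] = OptionDoc(process, option_token, value_kind, description, required)
        return self

    def include_module(self, other: "ProgramSpec") -> "ProgramSpec":
        """Merge another module's processes and docs.  Idempotent."""
        if other.module_name in self._included or other.module_name == self.module_name:
            return self
        for name in other._processes:
            if name in self._processes:
                raise DuplicateNameError(
                    f"process {name!r} defined in both module "
                    f"{self._process_module[name]!r} and module {other.module_name!r}"
                )
        for name, spec in other._processes.items():
            self._processes[name] = spec
            self._process_module[name] = other._process_module[name]
        for key, doc in other._docs.items():
            if key in self._docs:
                raise DuplicateNameError(
                    f"option {key[1]!r} for process {key[0]!r} documented in both "
                    f"module {self.module_name!r} and module {other.module_name!r}"
                )
            self._docs[key] = doc
        self._included.add(other.module_name)
        self._included |= other._included
        return self

    # -- access -------------------------------------------------------------

    @property
    def processes(self) -> list[ProcessSpec]:
        return list(self._processes.values())

    @property
    def process_names(self) -> list[str]:
        return list(self._processes)

    def process(self, name: str) -> ProcessSpec:
        try:
            return self._processes[name]
        except KeyError:
            from .errors import UnknownProcessError

            raise UnknownProcessError(f"unknown process {name!r}") from None

    def has_process(self, name: str) -> bool:
        return name in self._processes

    @property
    def option_docs(self) -> Mapping[tuple[str, str], OptionDoc]:
        return dict(self._docs)

    def documented_tokens(self) -> set[str]:
        return {token for (_proc, token) in self._docs}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProgramSpec):
            return NotImplemented
        return (
            self.module_name == other.module_name
            and self._processes == other._processes
            and self._docs == other._docs
        )


# ---------------------------------------------------------------------------
# Help rendering
# ---------------------------------------------------------------------------


def render_help(program: ProgramSpec) -> str:
    """Stable line-oriented help text built from documented options."""
    out = io.StringIO()
    out.write(f"program: {program.module_name}\n")
    docs = program.option_docs
    for spec in program.processes:
        proc_docs = [d for (p, _t), d in docs.items() if p == spec.name]
        if not proc_docs:
            continue
        out.write(f"\n{spec.name}:\n")
        for doc in proc_docs:
            req = "required" if doc.required else "optional"
            desc = doc.description if doc.description else "(undocumented)"
            out.write(f"  {doc.token} <{doc.value_kind}> [{req}] {desc}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Serialization (declarative programs only)
# ---------------------------------------------------------------------------

_DIRECTIVE_TAGS = {
    CmdlineOpt: "cmdline",
    ValueOpt: "value",
    FromProcessOut: "from_process_out",
    FifoOpt: "fifo",
    OutFile: "out_file",
}


def _directive_to_dict(d: Directive) -> dict:
    out = {"kind": _DIRECTIVE_TAGS[type(d)], "token": d.token}
    if isinstance(d, ValueOpt):
        out["value"] = d.value
    elif isinstance(d, FromProcessOut):
        out["producer"] = d.producer
        out["producer_token"] = d.producer_token
    elif isinstance(d, OutFile):
        out["filename"] = d.filename
    return out


def _directive_from_dict(d: Mapping) -> Directive:
    kind = d.get("kind")
    if kind == "cmdline":
        return CmdlineOpt(d["token"])
    if kind == "value":
        return ValueOpt(d["token"], str(d["value"]))
    if kind == "from_process_out":
        return FromProcessOut(d["token"], d["producer"], d["producer_token"])
    if kind == "fifo":
        return FifoOpt(d["token"])
    if kind == "out_file":
        return OutFile(d["token"], d["filename"])
    raise DefinitionError(f"unknown directive kind {kind!r}")


def dump_program(program: ProgramSpec) -> str:
    """Serialize to the versioned plain-text program definition format.

    Only declarative programs round-trip: generator connection rules and
    native-callable bodies are code, not data.
    """
    procs = []
    for spec in program.processes:
        if spec.connect is None:
            raise DefinitionError(
                f"process {spec.name}: generator connection rules are not serializable"
            )
        if spec.body.form == "native_callable":
            raise DefinitionError(
                f"process {spec.name}: native-callable bodies are not serializable"
            )
        procs.append(
            {
                "name": spec.name,
                "exec_class": spec.exec_class,
                "task_count": spec.task_count,
                "resources": {
                    "cpus": spec.resources.cpus,
                    "mem_mb": spec.resources.mem_mb,
                    "time_min": spec.resources.time_min,
                },
                "body": {
                    "form": spec.body.form,
                    "text": spec.body.text,
                    "interpreter": spec.body.interpreter,
                },
                "ports": [
                    {
                        "token": p.option_token,
                        "payload": p.payload,
                        "required": p.required,
                        "doc": p.doc,
                        "value_kind": p.value_kind,
                    }
                    for p in spec.ports
                ],
                "connect": [_directive_to_dict(d) for d in spec.connect],
            }
        )
    doc = {
        "fifoflow_program": SCHEMA_VERSION,
        "module": program.module_name,
        "processes": procs,
        "options": [
            {
                "process": d.process,
                "token": d.token,
                "value_kind": d.value_kind,
                "description": d.description,
                "required": d.required,
            }
            for d in program.option_docs.values()
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


def load_program(text: str) -> ProgramSpec:
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "fifoflow_program" not in doc:
        raise DefinitionError("not a fifoflow program definition")
    if doc["fifoflow_program"] != SCHEMA_VERSION:
        raise DefinitionError(
            f"unsupported program schema version {doc['fifoflow_program']!r}"
        )
    program = ProgramSpec(doc["module"])
    for p in doc.get("processes", ()):
        res = p.get("resources", {})
        spec = ProcessSpec(
            name=p["name"],
            body=BodySpec(
                form=p["body"]["form"],
                text=p["body"]["text"],
                interpreter=p["body"].get("interpreter", ""),
            ),
            ports=tuple(
                PortSpec(
                    option_token=q["token"],
                    payload=q.get("payload", "value"),
                    required=q.get("required", True),
                    doc=q.get("doc", ""),
                    value_kind=q.get("value_kind", "string"),
                )
                for q in p.get("ports", ())
            ),
            exec_class=p.get("exec_class"),
            resources=Resources(
                cpus=res.get("cpus", 1),
                mem_mb=res.get("mem_mb", 256),
                time_min=res.get("time_min", 60),
            ),
            task_count=p.get("task_count", 1),
            connect=tuple(_directive_from_dict(d) for d in p.get("connect", ())),
        )
        program.register_process(spec)
    for d in doc.get("options", ()):
        program.document_option(
            d["process"],
            d["token"],
            d.get("value_kind", "string"),
            d.get("description", ""),
            d.get("required", True),
        )
    return program
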