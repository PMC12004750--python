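"""Bundled example programs and their reference oracles.

The gallery ships four families of programs:

* **telegram** — the classic four-process text reflow network (``rseq ->
  decomposer -> recomposer -> wseq``) over stream channels, plus a
  job-step variant (``telegram_steps``) wired through files;
* **master_worker** — a cyclic two-process network with a stateful worker,
  plus a triggered/interactive variant exposing the ``master_trigger`` and
  ``worker_threshold`` FIFOs, and a dynamic-scheduling variant where the
  worker submits each transformation as a runtime computation;
* **counter / stream_echo** — two single-process programs whose exposed
  ``counter_out`` / ``stream_echo_in`` FIFOs demonstrate runtime piping;
* **host_process / host_workflow** — array job-step programs (each task
  runs ``hostname``) exercising the static scheduler.

The pure functions (:func:`telegram_reflow`, :func:`decompose`,
:func:`master_worker_oracle`, :func:`counter_stream`) are the ground truth
the engine-level tests compare against.
"""

from __future__ import annotations

from typing import Callable, Sequence

from .errors import DefinitionError
from .program_model import (
    BodySpec,
    CmdlineOpt,
    FifoOpt,
    FromProcessOut,
    OutFile,
    PortSpec,
    ProcessSpec,
    ProgramSpec,
)

__all__ = [
    "telegram_reflow",
    "decompose",
    "master_worker_oracle",
    "counter_stream",
    "build_telegram",
    "build_telegram_steps",
    "build_master_worker",
    "build_master_worker_triggered",
    "build_master_worker_dynamic",
    "build_counter",
    "build_stream_echo",
    "build_host_process",
    "build_host_workflow",
    "CATALOG",
]


# ---------------------------------------------------------------------------
# Pure oracles
# ---------------------------------------------------------------------------


def telegram_reflow(words: Sequence[str], limit: int) -> list[str]:
    """Greedy line packing: append a word iff the line stays within *limit*.

    Words are joined by single spaces; no word may exceed *limit* (that is
    a precondition, violated input raises).  The concatenation of output
    words equals the input and every output line is non-empty and maximal.
    """
    lines: list[str] = []
    current = ""
    for word in words:
        if len(word) > limit:
            raise DefinitionError(
                f"word {word!r} exceeds the line limit {limit}"
            )
        if not current:
            current = word
        elif len(current) + 1 + len(word) <= limit:
            current += " " + word
        else:
            lines.append(current)
            current = word
    if current:
        lines.append(current)
    return lines


def decompose(lines: Sequence[str]) -> list[str]:
    """Whitespace-delimited tokens in order; runs of whitespace collapse."""
    return [word for line in lines for word in line.split()]


def master_worker_oracle(v0: int, threshold: int, n_stop: int) -> dict:
    """Sequential simulation of the cyclic master-worker program.

    The worker adds 1 to the received value while its cumulative total is
    at or below *threshold*, else 2, accumulating each transformed value;
    the master stops once a returned value exceeds *n_stop*.  The threshold
    comparison uses the cumulative value *before* adding the current
    result.  Returns the last transformed value, the worker's cumulative
    total, and the cycle count.
    """
    cum = 0
    v = v0
    n_cycles = 0
    while True:
        inc = 1 if cum <= threshold else 2
        out = v + inc
        cum += out
        n_cycles += 1
        if out > n_stop:
            return {"final_value": out, "worker_cum": cum, "n_cycles": n_cycles}
        v = out


def counter_stream(n: int) -> list[str]:
    """Records ``"0" .. "n"`` inclusive; negative *n* is an error."""
    if n < 0:
        raise DefinitionError("counter bound must be non-negative")
    return [str(i) for i in range(n + 1)]


# ---------------------------------------------------------------------------
# Process bodies
# ---------------------------------------------------------------------------

_OPT_SNIPPET = '''\
import sys


def opt(token, default=None):
    argv = sys.argv[1:]
    for i in range(len(argv) - 1):
        if argv[i] == token:
            return argv[i + 1]
    return default


class FifoLineReader:
    """Reads lines from a FIFO, transparently reopening after each EOF so
    external writers can connect repeatedly."""

    def __init__(self, path):
        self.path = path
        self.fh = None

    def next(self):
        while True:
            if self.fh is None:
                self.fh = open(self.path)
            line = self.fh.readline()
            if line:
                return line
            self.fh.close()
            self.fh = None
'''

_RSEQ_BODY = """\
f=""; outf=""
while [ $# -gt 0 ]; do
  case "$1" in
    -f) f="$2"; shift 2;;
    -outf) outf="$2"; shift 2;;
    *) shift;;
  esac
done
cat -- "$f" > "$outf"
"""

_DECOMPOSER_BODY = (
    _OPT_SNIPPET
    + """

with open(opt("-inf")) as src, open(opt("-outf"), "w") as dst:
    for line in src:
        for word in line.split():
            dst.write(word + "\\n")
"""
)

_RECOMPOSER_BODY = (
    _OPT_SNIPPET
    + """

limit = int(opt("-l"))
current = ""
with open(opt("-inf")) as src, open(opt("-outf"), "w") as dst:
    for raw in src:
        word = raw.strip()
        if not word:
            continue
        if len(word) > limit:
            sys.stderr.write("word longer than the line limit\\n")
            sys.exit(1)
        if not current:
            current = word
        elif len(current) + 1 + len(word) <= limit:
            current += " " + word
        else:
            dst.write(current + "\\n")
            current = word
    if current:
        dst.write(current + "\\n")
"""
)

_WSEQ_BODY = """\
inf=""; outf=""
while [ $# -gt 0 ]; do
  case "$1" in
    -inf) inf="$2"; shift 2;;
    -outf) outf="$2"; shift 2;;
    *) shift;;
  esac
done
cat -- "$inf" > "$outf"
"""

_MASTER_BODY = (
    _OPT_SNIPPET
    + """

v = int(opt("-invalue"))
n_stop = int(opt("-inn"))
w = open(opt("-out"), "w")
w.write(str(v) + "\\n")
w.flush()
r = open(opt("-in"))
while True:
    line = r.readline()
    if not line:
        break
    out = int(line)
    if out > n_stop:
        break
    w.write(str(out) + "\\n")
    w.flush()
w.close()
r.close()
"""
)

_WORKER_BODY = (
    _OPT_SNIPPET
    + """

threshold = int(opt("-inthreshold"))
cum = 0
r = open(opt("-in"))
w = None
for line in r:
    v = int(line)
    inc = 1 if cum <= threshold else 2
    out = v + inc
    cum += out
    if w is None:
        w = open(opt("-out"), "w")
    w.write(str(out) + "\\n")
    w.flush()
r.close()
if w is not None:
    w.close()
print(cum)
"""
)

_MASTER_TRIGGERED_BODY = (
    _OPT_SNIPPET
    + """

trigger = FifoLineReader(opt("-intrigger"))
n_stop = int(opt("-inn"))
out_path = opt("-out")
in_path = opt("-in")
while True:
    v = int(trigger.next())
    w = open(out_path, "w")
    w.write(str(v) + "\\n")
    w.flush()
    r = open(in_path)
    while True:
        line = r.readline()
        if not line:
            break
        out = int(line)
        if out > n_stop:
            break
        w.write(str(out) + "\\n")
        w.flush()
    w.close()
    r.close()
"""
)

_WORKER_TRIGGERED_BODY = (
    _OPT_SNIPPET
    + """

thresholds = FifoLineReader(opt("-inthreshold"))
in_path = opt("-in")
out_path = opt("-out")
while True:
    cum = 0
    got_any = False
    r = open(in_path)
    w = None
    for line in r:
        got_any = True
        v = int(line)
        threshold = int(thresholds.next())
        inc = 1 if cum <= threshold else 2
        out = v + inc
        cum += out
        if w is None:
            w = open(out_path, "w")
        w.write(str(out) + "\\n")
        w.flush()
    r.close()
    if w is not None:
        w.close()
        w = None
    if got_any:
        print(cum, flush=True)
"""
)

_WORKER_DYNAMIC_BODY = (
    _OPT_SNIPPET
    + """

from fifoflow.dynamic_scheduler import submit_from_process, wait_from_process

outdir = opt("-outdir")
threshold = int(opt("-inthreshold"))
cum = 0
seq = 0
r = open(opt("-in"))
w = None
for line in r:
    v = int(line)
    inc = 1 if cum <= threshold else 2
    seq += 1
    tag = submit_from_process(outdir, "worker", "echo $(( %d + %d ))" % (v, inc), tag=seq)
    state, workdir = wait_from_process(outdir, "worker", tag)
    if state != "done":
        sys.exit(1)
    out = int(open(workdir / "out").read())
    cum += out
    if w is None:
        w = open(opt("-out"), "w")
    w.write(str(out) + "\\n")
    w.flush()
r.close()
if w is not None:
    w.close()
print(cum)
"""
)

_COUNTER_BODY = (
    _OPT_SNIPPET
    + """

n = int(opt("-inn"))
if n < 0:
    sys.stderr.write("counter bound must be non-negative\\n")
    sys.exit(1)
w = open(opt("-out"), "w")
for i in range(n + 1):
    w.write(str(i) + "\\n")
    w.flush()
w.close()
"""
)

_STREAM_ECHO_BODY = (
    _OPT_SNIPPET
    + """

with open(opt("-in")) as r:
    for line in r:
        sys.stdout.write(line)
        sys.stdout.flush()
"""
)

_HOST_BODY = """\
outf=""
while [ $# -gt 0 ]; do
  case "$1" in
    -outf) outf="$2"; shift 2;;
    *) shift;;
  esac
done
hostname > "$outf"
"""


def _py(text: str) -> BodySpec:
    return BodySpec.script(text, "python")


# ---------------------------------------------------------------------------
# Program builders
# ---------------------------------------------------------------------------


def build_telegram() -> ProgramSpec:
    """The four-process Telegram reflow network over stream channels."""
    program = ProgramSpec("telegram")
    program.register_process(
        ProcessSpec(
            name="rseq",
            body=BodySpec.command(_RSEQ_BODY),
            ports=(
                PortSpec("-f", payload="path", value_kind="path"),
                PortSpec("-outf", payload="stream"),
            ),
            connect=(CmdlineOpt("-f"),),
        )
    )
    program.register_process(
        ProcessSpec(
            name="decomposer",
            body=_py(_DECOMPOSER_BODY),
            ports=(
                PortSpec("-inf", payload="stream"),
                PortSpec("-outf", payload="stream"),
            ),
            connect=(FromProcessOut("-inf", "rseq", "-outf"),),
        )
    )
    program.register_process(
        ProcessSpec(
            name="recomposer",
            body=_py(_RECOMPOSER_BODY),
            ports=(
                PortSpec("-inf", payload="stream"),
                PortSpec("-l", payload="value", value_kind="int"),
                PortSpec("-outf", payload="stream"),
            ),
            connect=(
                FromProcessOut("-inf", "decomposer", "-outf"),
                CmdlineOpt("-l"),
            ),
        )
    )
    program.register_process(
        ProcessSpec(
            name="wseq",
            body=BodySpec.command(_WSEQ_BODY),
            ports=(
                PortSpec("-inf", payload="stream"),
                PortSpec("-outf", payload="path", value_kind="path"),
            ),
            exec_class="fbp_process",
            connect=(
                FromProcessOut("-inf", "recomposer", "-outf"),
                OutFile("-outf", "output.txt"),
            ),
        )
    )
    program.document_option("rseq", "-f", "path", "input file")
    program.document_option(
        "recomposer", "-l", "int", "maximum line length in characters"
    )
    return program


def build_telegram_steps() -> ProgramSpec:
    """Telegram wired through files: four job steps, reactive or static."""
    program = ProgramSpec("telegram_steps")
    program.register_process(
        ProcessSpec(
            name="rseq",
            body=BodySpec.command(_RSEQ_BODY),
            ports=(
                PortSpec("-f", payload="path", value_kind="path"),
                PortSpec("-outf", payload="path"),
            ),
            connect=(CmdlineOpt("-f"), OutFile("-outf", "lines.txt")),
        )
    )
    program.register_process(
        ProcessSpec(
            name="decomposer",
            body=_py(_DECOMPOSER_BODY),
            ports=(
                PortSpec("-inf", payload="path"),
                PortSpec("-outf", payload="path"),
            ),
            connect=(
                FromProcessOut("-inf", "rseq", "-outf"),
                OutFile("-outf", "words.txt"),
            ),
        )
    )
    program.register_process(
        ProcessSpec(
            name="recomposer",
            body=_py(_RECOMPOSER_BODY),
            ports=(
                PortSpec("-inf", payload="path"),
                PortSpec("-l", payload="value", value_kind="int"),
                PortSpec("-outf", payload="path"),
            ),
            connect=(
                FromProcessOut("-inf", "decomposer", "-outf"),
                CmdlineOpt("-l"),
                OutFile("-outf", "lines.txt"),
            ),
        )
    )
    program.register_process(
        ProcessSpec(
            name="wseq",
            body=BodySpec.command(_WSEQ_BODY),
            ports=(
                PortSpec("-inf", payload="path"),
                PortSpec("-outf", payload="path", value_kind="path"),
            ),
            connect=(
                FromProcessOut("-inf", "recomposer", "-outf"),
                OutFile("-outf", "output.txt"),
            ),
        )
    )
    program.document_option("rseq", "-f", "path", "input file")
    program.document_option(
        "recomposer", "-l", "int", "maximum line length in characters"
    )
    return program


def build_master_worker() -> ProgramSpec:
    """Cyclic master-worker network with a stateful worker."""
    program = ProgramSpec("master_worker")
    program.register_process(
        ProcessSpec(
            name="master",
            body=_py(_MASTER_BODY),
            ports=(
                PortSpec("-invalue", payload="value", value_kind="int"),
                PortSpec("-inn", payload="value", value_kind="int"),
                PortSpec("-out", payload="stream"),
                PortSpec("-in", payload="stream"),
            ),
            connect=(
                CmdlineOpt("-invalue"),
                CmdlineOpt("-inn"),
                FromProcessOut("-in", "worker", "-out"),
            ),
        )
    )
    program.register_process(
        ProcessSpec(
            name="worker",
            body=_py(_WORKER_BODY),
            ports=(
                PortSpec("-in", payload="stream"),
                PortSpec("-inthreshold", payload="value", value_kind="int"),
                PortSpec("-out", payload="stream"),
            ),
            connect=(
                FromProcessOut("-in", "master", "-out"),
                CmdlineOpt("-inthreshold"),
            ),
        )
    )
    program.document_option("master", "-invalue", "int", "initial value")
    program.document_option("master", "-inn", "int", "stop once a value exceeds this")
    program.document_option("worker", "-inthreshold", "int", "increment threshold")
    return program


def build_master_worker_triggered() -> ProgramSpec:
    """Master-worker with an external trigger FIFO (``master_trigger``) and
    an interactive per-cycle threshold FIFO (``worker_threshold``)."""
    program = ProgramSpec("master_worker_triggered")
    program.register_process(
        ProcessSpec(
            name="master",
            body=_py(_MASTER_TRIGGERED_BODY),
            ports=(
                PortSpec("-intrigger", payload="stream"),
                PortSpec("-inn", payload="value", value_kind="int"),
                PortSpec("-out", payload="stream"),
                PortSpec("-in", payload="stream"),
            ),
            connect=(
                FifoOpt("-intrigger"),
                CmdlineOpt("-inn"),
                FromProcessOut("-in", "worker", "-out"),
            ),
        )
    )
    program.register_process(
        ProcessSpec(
            name="worker",
            body=_py(_WORKER_TRIGGERED_BODY),
            ports=(
                PortSpec("-in", payload="stream"),
                PortSpec("-inthreshold", payload="stream"),
                PortSpec("-out", payload="stream"),
            ),
            connect=(
                FromProcessOut("-in", "master", "-out"),
                FifoOpt("-inthreshold"),
            ),
        )
    )
    program.document_option("master", "-inn", "int", "stop once a value exceeds this")
    return program


def build_master_worker_dynamic() -> ProgramSpec:
    """Master-worker where the worker submits each transformation as a
    runtime computation instead of computing locally."""
    program = build_master_worker()
    base_worker = program.process("worker")
    dynamic = ProgramSpec("master_worker_dynamic")
    dynamic.register_process(program.process("master"))
    dynamic.register_process(
        ProcessSpec(
            name="worker",
            body=_py(_WORKER_DYNAMIC_BODY),
            ports=base_worker.ports
            + (PortSpec("-outdir", payload="value", value_kind="path"),),
            connect=base_worker.connect + (CmdlineOpt("-outdir"),),
        )
    )
    dynamic.document_option("master", "-invalue", "int", "initial value")
    dynamic.document_option("master", "-inn", "int", "stop once a value exceeds this")
    dynamic.document_option("worker", "-inthreshold", "int", "increment threshold")
    dynamic.document_option("worker", "-outdir", "path", "program output directory")
    return dynamic


def build_counter() -> ProgramSpec:
    program = ProgramSpec("counter_program")
    program.register_process(
        ProcessSpec(
            name="counter",
            body=_py(_COUNTER_BODY),
            ports=(
                PortSpec("-inn", payload="value", value_kind="int"),
                PortSpec("-out", payload="stream"),
            ),
            connect=(CmdlineOpt("-inn"), FifoOpt("-out")),
        )
    )
    program.document_option("counter", "-inn", "int", "count from zero to this")
    return program


def build_stream_echo() -> ProgramSpec:
    program = ProgramSpec("stream_echo_program")
    program.register_process(
        ProcessSpec(
            name="stream_echo",
            body=_py(_STREAM_ECHO_BODY),
            ports=(PortSpec("-in", payload="stream"),),
            connect=(FifoOpt("-in"),),
        )
    )
    return program


def _host_process_spec(
    name: str, n_tasks: int | None, upstream: str | None
) -> ProcessSpec:
    def _tasks(ctx):
        n = n_tasks
        if n is None:
            n = int(ctx.cmdline_value("-n", "1"))
        for i in range(n):
            directives = []
            if upstream is not None:
                directives.append(FromProcessOut("-inf", upstream, "-outf"))
            directives.append(OutFile("-outf", f"host.{i}"))
            yield directives

    ports = [PortSpec("-outf", payload="path")]
    if upstream is not None:
        ports.insert(0, PortSpec("-inf", payload="path"))
    return ProcessSpec(
        name=name,
        body=BodySpec.command(_HOST_BODY),
        ports=tuple(ports),
        connect_tasks=_tasks,
    )


def build_host_process(n_tasks: int | None = None) -> ProgramSpec:
    """One job-step process (``host1``) running ``hostname`` per task."""
    program = ProgramSpec("host_process")
    program.register_process(_host_process_spec("host1", n_tasks, None))
    program.document_option("host1", "-n", "int", "number of array tasks", False)
    return program


def build_host_workflow(n_tasks: int | None = None) -> ProgramSpec:
    """Two dependent array job steps: ``host1`` first, then ``host2``."""
    program = ProgramSpec("host_workflow")
    program.register_process(_host_process_spec("host1", n_tasks, None))
    program.register_process(_host_process_spec("host2", n_tasks, "host1"))
    program.document_option("host1", "-n", "int", "number of array tasks", False)
    return program


CATALOG: dict[str, Callable[[], ProgramSpec]] = {
    "telegram": build_telegram,
    "telegram_steps": build_telegram_steps,
    "master_worker": build_master_worker,
    "master_worker_triggered": build_master_worker_triggered,
    "master_worker_dynamic": build_master_worker_dynamic,
    "counter": build_counter,
    "stream_echo": build_stream_echo,
    "host_process": build_host_process,
    "host_workflow": build_host_workflow,
}
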