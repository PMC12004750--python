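"""Dynamic scheduling: reactive activation of job steps, and a computation
pool that lets running stateful processes submit further work at runtime.

Activation is event-driven: the executor sleeps on a condition variable and
is woken by producer-completion callbacks, never by filesystem polling.
The computation pool accepts submissions both through its Python API and
through a small spool-file protocol under ``__computations__/`` so that
process bodies (which are separate OS processes) can submit work too.
"""

from __future__ import annotations

import json
import os
import subprocess
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from .errors import ExecutionError
from .network_resolution import ResolvedNetwork
from .program_model import Resources
from .static_scheduler import LocalCapacity, allocate_local

__all__ = [
    "ActivationEvent",
    "ComputationHandle",
    "ReactiveExecutor",
    "ComputationPool",
    "submit_from_process",
    "wait_from_process",
]


@dataclass(frozen=True)
class ActivationEvent:
    process: str
    task_index: int
    trigger: str  # "inputs_ready" or "submitted_by:<process>"


# ---------------------------------------------------------------------------
# Reactive job-step executor
# ---------------------------------------------------------------------------


class ReactiveExecutor:
    """Run job steps as soon as every producer has completed.

    *run_task(process, task) -> int* launches one array task and blocks.
    Producers that are FBP processes (or resume-skipped steps) are marked
    complete from outside via :meth:`notify_done` / :meth:`notify_failed`.
    Independent steps overlap up to *capacity*.
    """

    def __init__(
        self,
        network: ResolvedNetwork,
        capacity: LocalCapacity,
        run_task: Callable[[str, int], int],
        on_task_state: Callable[[str, int, str], None] | None = None,
    ):
        self.network = network
        self.capacity = capacity
        self._run_task = run_task
        self._on_task_state = on_task_state or (lambda p, t, s: None)
        self._cond = threading.Condition()
        self._steps = list(network.job_steps())
        self._producers = {
            s: list(network.producers_of(s)) for s in self._steps
        }
        self._done: set[str] = set()  # completed processes (any class)
        self._failed: set[str] = set()
        self._cancelled: set[str] = set()
        self._skipped: set[str] = set()
        self.activations: list[ActivationEvent] = []

    # -- external notifications --------------------------------------------

    def notify_done(self, process: str) -> None:
        with self._cond:
            self._done.add(process)
            self._cond.notify_all()

    def notify_failed(self, process: str) -> None:
        with self._cond:
            self._failed.add(process)
            self._cond.notify_all()

    def skip(self, process: str) -> None:
        """Mark a step as resume-skipped: counts as completed, runs nothing."""
        with self._cond:
            self._skipped.add(process)
            self._done.add(process)
            self._cond.notify_all()

    # -- results ------------------------------------------------------------

    @property
    def failed_steps(self) -> set[str]:
        return set(self._failed) & set(self._steps)

    @property
    def cancelled_steps(self) -> set[str]:
        return set(self._cancelled)

    def run_to_completion(self) -> None:
        cpus_used = 0
        mem_used = 0
        in_flight = 0
        started: set[tuple[str, int]] = set()
        finished: dict[str, int] = {s: 0 for s in self._steps}
        task_failed: set[str] = set()
        pending = [s for s in self._steps if s not in self._skipped]

        def _resources(step: str) -> Resources:
            return self.network.program.process(step).resources

        def _cancel_downstream() -> None:
            changed = True
            while changed:
                changed = False
                for s in pending:
                    if s in self._cancelled or (s, 0) in started:
                        continue
                    if any(
                        p in self._failed or p in self._cancelled
                        for p in self._producers[s]
                    ):
                        self._cancelled.add(s)
                        changed = True
                        for t in range(self.network.task_counts[s]):
                            self._on_task_state(s, t, "stopped")

        def _worker(step: str, task: int) -> None:
            nonlocal cpus_used, mem_used, in_flight
            code = self._run_task(step, task)
            with self._cond:
                cpus_used -= _resources(step).cpus
                mem_used -= _resources(step).mem_mb
                in_flight -= 1
                finished[step] += 1
                if code != 0:
                    task_failed.add(step)
                if finished[step] == self.network.task_counts[step]:
                    if step in task_failed:
                        self._failed.add(step)
                    else:
                        self._done.add(step)
                self._cond.notify_all()

        with self._cond:
            while True:
                _cancel_downstream()
                unresolved = [
                    s
                    for s in pending
                    if s not in self._done
                    and s not in self._failed
                    and s not in self._cancelled
                ]
                if not unresolved:
                    break
                runnable: list[tuple[str, int]] = []
                for s in unresolved:
                    if not all(p in self._done for p in self._producers[s]):
                        continue
                    for t in range(self.network.task_counts[s]):
                        if (s, t) not in started:
                            runnable.append((s, t))
                sel = allocate_local(
                    [_resources(s) for s, _t in runnable],
                    LocalCapacity(
                        self.capacity.cpus - cpus_used,
                        self.capacity.mem_mb - mem_used,
                    ),
                )
                for k in sel:
                    s, t = runnable[k]
                    started.add((s, t))
                    self.activations.append(
                        ActivationEvent(process=s, task_index=t, trigger="inputs_ready")
                    )
                    cpus_used += _resources(s).cpus
                    mem_used += _resources(s).mem_mb
                    in_flight += 1
                    threading.Thread(
                        target=_worker, args=(s, t), daemon=True
                    ).start()
                if sel:
                    continue
                if in_flight > 0:
                    self._cond.wait()
                    continue
                # no running work; are we waiting on external producers?
                blocked_on_external = [
                    s
                    for s in unresolved
                    if any(
                        p not in self._done
                        and p not in self._steps
                        for p in self._producers[s]
                    )
                ]
                if blocked_on_external:
                    self._cond.wait()
                    continue
                # nothing can ever run (over-capacity tasks): fail them
                for s in unresolved:
                    if all(p in self._done for p in self._producers[s]):
                        self._failed.add(s)
                        for t in range(self.network.task_counts[s]):
                            self._on_task_state(s, t, "failed")


# ---------------------------------------------------------------------------
# Runtime computation submission
# ---------------------------------------------------------------------------

_REQ_SUFFIX = ".req"


@dataclass
class ComputationHandle:
    """A computation submitted at runtime by a stateful process."""

    id: str
    owner: str
    _pool: "ComputationPool" = field(repr=False)

    @property
    def state(self) -> str:
        return self._pool._handle_state(self.id)

    @property
    def exit_code(self) -> int | None:
        return self._pool._handle_exit(self.id)

    def wait(self, timeout: float | None = None) -> str:
        return self._pool._wait(self.id, timeout)


class ComputationPool:
    """Executes computations submitted at runtime, locally under a capacity.

    In-engine callers use :meth:`submit`; process bodies write spool files
    (see :func:`submit_from_process`) that a pool thread picks up.  Results
    land under ``__computations__/<owner>_<seq>/``.
    """

    SCAN_INTERVAL = 0.05

    def __init__(self, tree, capacity: LocalCapacity):
        self.tree = tree
        self.capacity = capacity
        self._cond = threading.Condition()
        self._states: dict[str, str] = {}
        self._exits: dict[str, int | None] = {}
        self._cpus_used = 0
        self._mem_used = 0
        self._seq = 0
        self._closed = False
        self._scanner: threading.Thread | None = None
        self.submissions: list[str] = []

    # -- lifecycle -----------------------------------------------------------

    def start(self) -> None:
        self.tree.computations_dir.mkdir(exist_ok=True)
        (self.tree.computations_dir / "requests").mkdir(exist_ok=True)
        self._scanner = threading.Thread(
            target=self._scan_loop, name="computation-pool", daemon=True
        )
        self._scanner.start()

    def close(self) -> None:
        with self._cond:
            self._closed = True
            self._cond.notify_all()
        if self._scanner is not None:
            self._scanner.join(timeout=5)

    def drain(self, timeout: float = 60.0) -> None:
        """Wait until every accepted computation reached a terminal state."""
        deadline = time.monotonic() + timeout
        with self._cond:
            while any(s in ("queued", "running") for s in self._states.values()):
                remaining = deadline - time.monotonic()
                if remaining <= 0:
                    raise ExecutionError("computation pool drain timed out")
                self._cond.wait(remaining)

    # -- submission ----------------------------------------------------------

    def submit(
        self,
        owner: str,
        command: str,
        resources: Resources | None = None,
    ) -> ComputationHandle:
        resources = resources or Resources()
        with self._cond:
            if self._closed:
                raise ExecutionError("computation pool is closed (program stopped)")
            self._seq += 1
            comp_id = f"{owner}_{self._seq}"
            self.submissions.append(comp_id)
            if (
                resources.cpus > self.capacity.cpus
                or resources.mem_mb > self.capacity.mem_mb
            ):
                self._states[comp_id] = "failed"
                self._exits[comp_id] = None
                self._write_status(comp_id, "failed", -1)
                return ComputationHandle(comp_id, owner, self)
            self._states[comp_id] = "queued"
            self._exits[comp_id] = None
        threading.Thread(
            target=self._execute,
            args=(comp_id, command, resources),
            daemon=True,
        ).start()
        return ComputationHandle(comp_id, owner, self)

    def _execute(self, comp_id: str, command: str, resources: Resources) -> None:
        with self._cond:
            while (
                self._cpus_used + resources.cpus > self.capacity.cpus
                or self._mem_used + resources.mem_mb > self.capacity.mem_mb
            ):
                if self._closed:
                    self._states[comp_id] = "failed"
                    self._write_status(comp_id, "failed", -1)
                    self._cond.notify_all()
                    return
                self._cond.wait()
            self._cpus_used += resources.cpus
            self._mem_used += resources.mem_mb
            self._states[comp_id] = "running"
        workdir = self.tree.computations_dir / comp_id
        workdir.mkdir(parents=True, exist_ok=True)
        try:
            with open(workdir / "out", "wb") as out, open(
                workdir / "err", "wb"
            ) as err:
                code = subprocess.run(
                    ["bash", "-c", command],
                    stdout=out,
                    stderr=err,
                    cwd=workdir,
                ).returncode
        except OSError:
            code = -1
        with self._cond:
            self._cpus_used -= resources.cpus
            self._mem_used -= resources.mem_mb
            self._states[comp_id] = "done" if code == 0 else "failed"
            self._exits[comp_id] = code
            self._cond.notify_all()
        self._write_status(comp_id, self._states[comp_id], code)

    def _write_status(self, comp_id: str, state: str, code: int | None) -> None:
        workdir = self.tree.computations_dir / comp_id
        workdir.mkdir(parents=True, exist_ok=True)
        tmp = workdir / ".status.tmp"
        tmp.write_text(f"{state}\t{code if code is not None else '-'}\n")
        os.replace(tmp, workdir / "status")

    # -- spool protocol ------------------------------------------------------

    def _scan_loop(self) -> None:
        req_dir = self.tree.computations_dir / "requests"
        while True:
            with self._cond:
                if self._closed:
                    return
            try:
                entries = sorted(req_dir.glob(f"*{_REQ_SUFFIX}"))
            except OSError:
                entries = []
            for path in entries:
                try:
                    req = json.loads(path.read_text())
                    path.unlink()
                except (OSError, json.JSONDecodeError):
                    continue
                resources = Resources(
                    cpus=int(req.get("cpus", 1)),
                    mem_mb=int(req.get("mem_mb", 256)),
                    time_min=int(req.get("time_min", 60)),
                )
                handle = self.submit(req["owner"], req["command"], resources)
                # map the caller-chosen tag onto the pool id so the body can
                # find the status file
                tag = req.get("tag")
                if tag is not None:
                    link = self.tree.computations_dir / f"tag_{req['owner']}_{tag}"
                    tmp = Path(str(link) + ".tmp")
                    tmp.write_text(handle.id + "\n")
                    os.replace(tmp, link)
            time.sleep(self.SCAN_INTERVAL)

    # -- handle plumbing -----------------------------------------------------

    def _handle_state(self, comp_id: str) -> str:
        with self._cond:
            return self._states[comp_id]

    def _handle_exit(self, comp_id: str) -> int | None:
        with self._cond:
            return self._exits[comp_id]

    def _wait(self, comp_id: str, timeout: float | None) -> str:
        deadline = None if timeout is None else time.monotonic() + timeout
        with self._cond:
            while self._states[comp_id] in ("queued", "running"):
                remaining = None
                if deadline is not None:
                    remaining = deadline - time.monotonic()
                    if remaining <= 0:
                        raise ExecutionError(f"timeout waiting for {comp_id}")
                self._cond.wait(remaining)
            return self._states[comp_id]


def run_reactive(network: ResolvedNetwork, root: os.PathLike | str, config=None):
    """Execute *network* under the reactive scheduler (see
    :func:`fifoflow.runtime_engine.execute`)."""
    from .runtime_engine import execute

    return execute(network, root, scheduler="dynamic", config=config)


# -- helpers used from inside process bodies --------------------------------


def submit_from_process(
    outdir: os.PathLike | str,
    owner: str,
    command: str,
    tag: str | int | None = None,
    cpus: int = 1,
    mem_mb: int = 256,
) -> str:
    """Submit a computation from a running process body (separate OS
    process) by dropping a spool file for the engine's pool.  Returns the
    tag used to await the result."""
    outdir = Path(outdir)
    req_dir = outdir / "__computations__" / "requests"
    req_dir.mkdir(parents=True, exist_ok=True)
    tag = str(tag) if tag is not None else f"{owner}_{time.monotonic_ns()}"
    payload = json.dumps(
        {"owner": owner, "command": command, "tag": tag, "cpus": cpus, "mem_mb": mem_mb}
    )
    tmp = req_dir / f".{owner}_{tag}.tmp"
    tmp.write_text(payload)
    os.replace(tmp, req_dir / f"{owner}_{tag}{_REQ_SUFFIX}")
    return tag


def wait_from_process(
    outdir: os.PathLike | str,
    owner: str,
    tag: str | int,
    timeout: float = 120.0,
    poll: float = 0.02,
) -> tuple[str, Path]:
    """Await a spool-submitted computation; returns (state, workdir)."""
    outdir = Path(outdir)
    comp_dir = outdir / "__computations__"
    link = comp_dir / f"tag_{owner}_{tag}"
    deadline = time.monotonic() + timeout
    while True:
        if link.exists():
            comp_id = link.read_text().strip()
            status = comp_dir / comp_id / "status"
            if status.exists():
                state = status.read_text().split("\t")[0]
                if state in ("done", "failed"):
                    return state, comp_dir / comp_id
        if time.monotonic() > deadline:
            raise ExecutionError(f"timeout waiting for computation {owner}/{tag}")
        time.sleep(poll)
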