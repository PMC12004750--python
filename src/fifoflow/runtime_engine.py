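"""Execute a resolved network.

All FBP processes are spawned at program start (after every FIFO exists)
and control their own life cycle; job steps run under the selected
scheduler.  Per-task life-cycle state is persisted under ``__exec__`` after
every transition, so a crashed engine — or a ``status``/``stop`` invocation
from another OS process — can always recover the truth from disk.

Life-cycle legality::

    pending -> in_progress -> {completed, failed}
    pending -> failed                (spawn failure)
    {pending, in_progress} -> stopped  (stop())

Terminal states never move.  Resume resets (completed -> pending when a
process's resolved options changed) are recorded as explicit ``reset``
events starting a fresh episode.
"""

from __future__ import annotations

import hashlib
import json
import os
import signal
import subprocess
import sys
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .channel_layer import OutputTree, materialize
from .dynamic_scheduler import ComputationPool, ReactiveExecutor
from .errors import ExecutionError, SchedulerError, UnboundInputError
from .network_resolution import ResolvedNetwork, export_graph
from .program_model import INPUT, NOT_FOUND, read_opt_value
from .static_scheduler import (
    LocalBackend,
    LocalCapacity,
    PlannedJob,
    SubmissionPlan,
    build_plan,
    dump_plan,
    submit_all,
)

__all__ = [
    "PENDING",
    "IN_PROGRESS",
    "COMPLETED",
    "FAILED",
    "STOPPED",
    "ExecutionState",
    "RunReport",
    "EngineConfig",
    "StateStore",
    "execute",
    "status",
    "stop",
    "invoke_inline",
]

PENDING = "pending"
IN_PROGRESS = "in_progress"
COMPLETED = "completed"
FAILED = "failed"
STOPPED = "stopped"

LEGAL_TRANSITIONS = {
    PENDING: {IN_PROGRESS, FAILED, STOPPED},
    IN_PROGRESS: {COMPLETED, FAILED, STOPPED},
    COMPLETED: set(),
    FAILED: set(),
    STOPPED: set(),
}

_INTERPRETERS = {
    "python": sys.executable,
    "python3": sys.executable,
}

_SCRIPT_SUFFIX = {
    "python": "py",
    "python3": "py",
    "bash": "sh",
    "sh": "sh",
    "perl": "pl",
    "Rscript": "R",
}


@dataclass(frozen=True)
class ExecutionState:
    process: str
    task_index: int
    status: str
    exit_code: int | None = None
    start_time: float | None = None
    end_time: float | None = None


@dataclass(frozen=True)
class RunReport:
    root: Path
    final_states: tuple[ExecutionState, ...]
    overall: str  # completed | failed | stopped

    @property
    def exit_code(self) -> int:
        return {"completed": 0, "failed": 1, "stopped": 2}[self.overall]


@dataclass
class EngineConfig:
    capacity: LocalCapacity = field(
        default_factory=lambda: LocalCapacity(
            cpus=max(4, os.cpu_count() or 1), mem_mb=16384
        )
    )
    deadlock_timeout: float = 30.0
    grace_period: float = 2.0


def _overall(states: Sequence[ExecutionState]) -> str:
    if any(s.status == STOPPED for s in states):
        return "stopped"
    if any(s.status in (FAILED, PENDING, IN_PROGRESS) for s in states):
        return "failed" if any(s.status == FAILED for s in states) else "stopped"
    return "completed"


# ---------------------------------------------------------------------------
# Persistent state store
# ---------------------------------------------------------------------------


class StateStore:
    """Append-only per-process transition logs plus a compacted snapshot.

    Log line format (tab-separated)::

        <task>  <status>  <exit_code|->  <unix_ts>  [reset]

    The snapshot is rewritten append-then-rename after every transition;
    the logs remain the source of truth.
    """

    def __init__(self, tree: OutputTree):
        self.tree = tree
        self.dir = tree.exec_dir / "status"
        self.dir.mkdir(parents=True, exist_ok=True)
        self._lock = threading.RLock()
        # (process, task) -> (status, exit_code, start, end)
        self._cache: dict[tuple[str, int], list] = {}
        self._load()

    def _log_path(self, process: str) -> Path:
        return self.dir / f"{process}.log"

    def _load(self) -> None:
        for path in sorted(self.dir.glob("*.log")):
            process = path.stem
            for task, status, exit_code, ts, _reset in self.history(process):
                key = (process, task)
                entry = self._cache.setdefault(key, [PENDING, None, None, None])
                entry[0] = status
                entry[1] = exit_code
                if status == IN_PROGRESS:
                    entry[2] = ts
                if status in (COMPLETED, FAILED, STOPPED):
                    entry[3] = ts

    def history(self, process: str):
        """Parsed transition log: (task, status, exit_code, ts, is_reset)."""
        path = self._log_path(process)
        if not path.exists():
            return []
        out = []
        for line in path.read_text().splitlines():
            parts = line.split("\t")
            if len(parts) < 4:
                continue
            task = int(parts[0])
            exit_code = None if parts[2] == "-" else int(parts[2])
            out.append(
                (task, parts[1], exit_code, float(parts[3]), len(parts) > 4)
            )
        return out

    def _append(self, process: str, task: int, status: str, exit_code, reset: bool):
        self._append_many(process, [(task, status, exit_code, reset)])

    def _append_many(self, process: str, rows) -> None:
        now = time.time()
        with open(self._log_path(process), "a") as fh:
            for task, status, exit_code, reset in rows:
                code = "-" if exit_code is None else str(exit_code)
                suffix = "\treset" if reset else ""
                fh.write(f"{task}\t{status}\t{code}\t{now:.6f}{suffix}\n")
            fh.flush()

    _SNAPSHOT_INTERVAL = 0.5  # the append-only logs are the source of truth

    def _snapshot(self, force: bool = False) -> None:
        now = time.monotonic()
        last = getattr(self, "_last_snapshot", 0.0)
        if not force and now - last < self._SNAPSHOT_INTERVAL:
            return
        self._last_snapshot = now
        tmp = self.dir / ".snapshot.tmp"
        with open(tmp, "w") as fh:
            for (process, task), (st, code, _s, _e) in sorted(self._cache.items()):
                c = "-" if code is None else str(code)
                fh.write(f"{process}\t{task}\t{st}\t{c}\n")
        os.replace(tmp, self.dir / "snapshot")

    def current(self, process: str, task: int) -> str:
        with self._lock:
            entry = self._cache.get((process, task))
            return entry[0] if entry else PENDING

    def set(
        self,
        process: str,
        task: int,
        status: str,
        exit_code: int | None = None,
    ) -> None:
        """Record a transition; raises on an illegal one."""
        if not self.try_set(process, task, status, exit_code):
            raise ExecutionError(
                f"illegal status transition for {process}[{task}]: "
                f"{self.current(process, task)} -> {status}"
            )

    def try_set(
        self,
        process: str,
        task: int,
        status: str,
        exit_code: int | None = None,
    ) -> bool:
        """Record a transition if legal; returns False otherwise.

        Setting the current status again is an allowed no-op (idempotent
        stop), recorded nowhere.
        """
        with self._lock:
            key = (process, task)
            entry = self._cache.get(key)
            cur = entry[0] if entry else None
            if cur == status:
                return True
            if cur is not None and status not in LEGAL_TRANSITIONS[cur]:
                return False
            now = time.time()
            if entry is None:
                entry = self._cache[key] = [status, exit_code, None, None]
            else:
                entry[0] = status
                entry[1] = exit_code
            if status == IN_PROGRESS:
                entry[2] = now
            if status in (COMPLETED, FAILED, STOPPED):
                entry[3] = now
            self._append(process, task, status, exit_code, reset=False)
            self._snapshot()
            return True

    def reset(self, process: str, n_tasks: int) -> None:
        """Start a fresh episode (resume with changed options)."""
        with self._lock:
            rows = []
            for task in range(n_tasks):
                self._cache[(process, task)] = [PENDING, None, None, None]
                rows.append((task, PENDING, None, True))
            if rows:
                self._append_many(process, rows)
            self._snapshot()

    def init_pending(self, process: str, n_tasks: int) -> None:
        with self._lock:
            rows = []
            for task in range(n_tasks):
                if (process, task) not in self._cache:
                    self._cache[(process, task)] = [PENDING, None, None, None]
                    rows.append((task, PENDING, None, False))
            if rows:
                self._append_many(process, rows)
            self._snapshot()

    def set_many(
        self,
        process: str,
        n_tasks: int,
        status: str,
        exit_code: int | None = None,
    ) -> None:
        """Batch transition for a whole array (one append, one snapshot)."""
        with self._lock:
            now = time.time()
            rows = []
            for task in range(n_tasks):
                key = (process, task)
                entry = self._cache.get(key)
                cur = entry[0] if entry else None
                if cur == status:
                    continue
                if cur is not None and status not in LEGAL_TRANSITIONS[cur]:
                    continue
                if entry is None:
                    entry = self._cache[key] = [status, exit_code, None, None]
                else:
                    entry[0] = status
                    entry[1] = exit_code
                if status == IN_PROGRESS:
                    entry[2] = now
                if status in (COMPLETED, FAILED, STOPPED):
                    entry[3] = now
                rows.append((task, status, exit_code, False))
            if rows:
                self._append_many(process, rows)
            self._snapshot()

    def states(self, order: Sequence[str] | None = None) -> list[ExecutionState]:
        with self._lock:
            keys = sorted(self._cache)
            if order is not None:
                rank = {name: i for i, name in enumerate(order)}
                keys.sort(key=lambda k: (rank.get(k[0], len(rank)), k[1]))
            return [
                ExecutionState(
                    process=p,
                    task_index=t,
                    status=e[0],
                    exit_code=e[1],
                    start_time=e[2],
                    end_time=e[3],
                )
                for (p, t) in keys
                for e in [self._cache[(p, t)]]
            ]


# ---------------------------------------------------------------------------
# Body launching
# ---------------------------------------------------------------------------


def _interpreter_command(name: str) -> str:
    return _INTERPRETERS.get(name, name)


class _Launcher:
    def __init__(self, network: ResolvedNetwork, tree: OutputTree, store: StateStore):
        self.network = network
        self.tree = tree
        self.store = store
        self._pid_lock = threading.Lock()
        self._pids: dict[tuple[str, int], int] = {}

    # -- plumbing ------------------------------------------------------------

    def script_path(self, process: str) -> Path:
        spec = self.network.program.process(process)
        scripts = self.tree.exec_dir / "scripts"
        scripts.mkdir(exist_ok=True)
        suffix = _SCRIPT_SUFFIX.get(spec.body.interpreter, "txt")
        path = scripts / f"{process}.{suffix}"
        if not path.exists() or path.read_text() != spec.body.text:
            path.write_text(spec.body.text)  # byte-exact, no escaping
        return path

    def out_paths(self, process: str, task: int) -> tuple[Path, Path]:
        d = self.tree.process_dir(process)
        if self.network.task_counts[process] == 1:
            return d / "stdout", d / "stderr"
        return d / f"stdout_{task}", d / f"stderr_{task}"

    def command(self, process: str, argv: Sequence[str]) -> list[str]:
        spec = self.network.program.process(process)
        body = spec.body
        if body.form == "command_text":
            return ["bash", "-c", body.text, process, *argv]
        if body.form == "inline_script":
            return [
                _interpreter_command(body.interpreter),
                str(self.script_path(process)),
                *argv,
            ]
        raise ExecutionError(f"cannot build a command for body form {body.form!r}")

    def _record_pid(self, process: str, task: int, pid: int) -> None:
        with self._pid_lock:
            self._pids[(process, task)] = pid
            with open(self.tree.exec_dir / "pids", "a") as fh:
                fh.write(f"{pid}\t{process}\t{task}\n")

    # -- execution -----------------------------------------------------------

    def spawn(self, process: str, task: int = 0) -> subprocess.Popen | None:
        """Start a process body asynchronously in its own process group."""
        argv = self.network.argv(process, task, self.tree)
        spec = self.network.program.process(process)
        out_path, err_path = self.out_paths(process, task)
        if spec.body.form == "native_callable":
            raise ExecutionError(
                "native-callable bodies cannot run as FBP processes"
            )
        self.store.try_set(process, task, IN_PROGRESS)
        try:
            proc = subprocess.Popen(
                self.command(process, argv),
                stdout=open(out_path, "wb"),
                stderr=open(err_path, "wb"),
                cwd=self.tree.process_dir(process),
                start_new_session=True,
            )
        except OSError as exc:
            self.store.try_set(process, task, FAILED, exit_code=127)
            with open(err_path, "ab") as fh:
                fh.write(f"spawn failure: {exc}\n".encode())
            return None
        self._record_pid(process, task, proc.pid)
        return proc

    def run_task(self, process: str, task: int) -> int:
        """Run one job-step task synchronously; persists its transitions."""
        spec = self.network.program.process(process)
        argv = self.network.argv(process, task, self.tree)
        out_path, err_path = self.out_paths(process, task)
        if not self.store.try_set(process, task, IN_PROGRESS):
            return 1  # already terminal (stopped under our feet)
        if spec.body.form == "native_callable":
            with open(out_path, "w") as out, open(err_path, "w") as err:
                try:
                    code = spec.body.fn(list(argv), out, err)
                    code = 0 if code is None else int(code)
                except Exception as exc:  # body errors are task failures
                    err.write(f"{type(exc).__name__}: {exc}\n")
                    code = 1
        else:
            try:
                with open(out_path, "wb") as out, open(err_path, "wb") as err:
                    proc = subprocess.Popen(
                        self.command(process, argv),
                        stdout=out,
                        stderr=err,
                        cwd=self.tree.process_dir(process),
                        start_new_session=True,
                    )
                    self._record_pid(process, task, proc.pid)
                    code = proc.wait()
            except OSError:
                code = 127
        if code == 0:
            self.store.try_set(process, task, COMPLETED, exit_code=0)
        elif self.stop_requested():
            self.store.try_set(process, task, STOPPED, exit_code=code)
        else:
            self.store.try_set(process, task, FAILED, exit_code=code)
        return code

    def stop_requested(self) -> bool:
        return (self.tree.exec_dir / "stop").exists()


# ---------------------------------------------------------------------------
# Resume fingerprints
# ---------------------------------------------------------------------------


def _fingerprints(network: ResolvedNetwork, tree: OutputTree) -> dict[str, str]:
    out = {}
    for name in network.program.process_names:
        rows = [
            network.argv(name, task, tree)
            for task in range(network.task_counts[name])
        ]
        blob = json.dumps(rows, sort_keys=True).encode()
        out[name] = hashlib.sha256(blob).hexdigest()
    return out


def _load_fingerprints(tree: OutputTree) -> dict[str, str]:
    path = tree.exec_dir / "fingerprints.json"
    if not path.exists():
        return {}
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError:
        return {}


def _save_fingerprints(tree: OutputTree, fp: dict[str, str]) -> None:
    tmp = tree.exec_dir / ".fingerprints.tmp"
    tmp.write_text(json.dumps(fp, sort_keys=True, indent=0))
    os.replace(tmp, tree.exec_dir / "fingerprints.json")


# ---------------------------------------------------------------------------
# execute / status / stop
# ---------------------------------------------------------------------------


def execute(
    network: ResolvedNetwork,
    root: os.PathLike | str,
    scheduler: str = "dynamic",
    backend=None,
    config: EngineConfig | None = None,
) -> RunReport:
    """Run the network to completion and return the persisted final states.

    ``scheduler="dynamic"`` spawns every FBP process up front and activates
    job steps reactively; ``scheduler="static"`` compiles a submission plan
    and pushes it through *backend* (default: the built-in local allocator)
    in a single pass.
    """
    if scheduler not in ("dynamic", "static"):
        raise SchedulerError(f"unknown scheduler {scheduler!r}")
    config = config or EngineConfig()
    tree = materialize(network, root)
    (tree.graphs_dir / "process.dot").write_text(export_graph(network, "process"))
    (tree.graphs_dir / "dependency.dot").write_text(
        export_graph(network, "dependency")
    )
    (tree.exec_dir / "stop").unlink(missing_ok=True)
    store = StateStore(tree)
    launcher = _Launcher(network, tree, store)

    # resume: skip processes whose tasks all completed with unchanged options
    # — and whose upstream producers are themselves skipped (a re-run
    # producer regenerates inputs, so dependents must re-run too)
    fp = _fingerprints(network, tree)
    prev = _load_fingerprints(tree)
    skipped: set[str] = set()
    for name in network.program.process_names:
        n = network.task_counts[name]
        statuses = [store.current(name, t) for t in range(n)]
        if (
            statuses
            and all(s == COMPLETED for s in statuses)
            and prev.get(name) == fp[name]
        ):
            skipped.add(name)
    changed = True
    while changed:
        changed = False
        for name in list(skipped):
            if any(p not in skipped for p in network.producers_of(name)):
                skipped.discard(name)
                changed = True
    for name in network.program.process_names:
        if name in skipped:
            continue
        n = network.task_counts[name]
        statuses = [store.current(name, t) for t in range(n)]
        if any(s in (COMPLETED, FAILED, STOPPED, IN_PROGRESS) for s in statuses):
            store.reset(name, n)
    _save_fingerprints(tree, fp)
    for name in network.program.process_names:
        if name not in skipped:
            store.init_pending(name, network.task_counts[name])

    if scheduler == "static":
        _run_static(network, tree, store, launcher, backend, config, skipped)
    else:
        _run_dynamic(network, tree, store, launcher, config, skipped)

    store._snapshot(force=True)
    states = store.states(order=network.program.process_names)
    return RunReport(
        root=Path(root), final_states=tuple(states), overall=_overall(states)
    )


def _run_static(network, tree, store, launcher, backend, config, skipped) -> None:
    plan = build_plan(network)
    (tree.exec_dir / "plan").write_text(dump_plan(plan))
    live_jobs = tuple(
        PlannedJob(
            job_key=j.job_key,
            array_size=j.array_size,
            resources=j.resources,
            depends_on=tuple(d for d in j.depends_on if d not in skipped),
            dependency_type=j.dependency_type,
        )
        for j in plan.jobs
        if j.job_key not in skipped
    )
    live_plan = SubmissionPlan(jobs=live_jobs)
    if backend is None:
        backend = LocalBackend(
            config.capacity,
            run_task=launcher.run_task,
            cancel_task=lambda p, t: store.try_set(p, t, STOPPED),
        )
    executes_bodies = isinstance(backend, LocalBackend)
    id_to_key: dict[str, str] = {}

    def _on_complete(backend_id: str, state: str) -> None:
        key = id_to_key.get(backend_id)
        if key is None or executes_bodies:
            return  # local backend updates per-task state via run_task
        n = network.task_counts[key]
        if state == "done":
            store.set_many(key, n, IN_PROGRESS)
            store.set_many(key, n, COMPLETED, exit_code=0)
        elif state == "failed":
            store.set_many(key, n, FAILED, exit_code=1)
        else:
            store.set_many(key, n, STOPPED)

    backend.on_complete(_on_complete)
    ids = submit_all(live_plan, backend)
    id_to_key.update({v: k for k, v in ids.items()})
    # single submission pass done: from here the engine only waits
    backend.run_to_completion()


def _run_dynamic(network, tree, store, launcher, config, skipped) -> None:
    pool = ComputationPool(tree, config.capacity)
    pool.start()
    executor = ReactiveExecutor(
        network,
        config.capacity,
        run_task=launcher.run_task,
        on_task_state=lambda p, t, s: store.try_set(p, t, s),
    )
    fbp = network.fbp_processes()
    watchers: list[threading.Thread] = []
    procs: dict[str, subprocess.Popen] = {}
    activity = threading.Event()  # set once all fbp procs finished

    for name in network.job_steps():
        if name in skipped:
            executor.skip(name)

    def _kill_dependents(failed_proc: str) -> None:
        # transitive closure over process-port channels
        dependents: set[str] = set()
        frontier = [failed_proc]
        while frontier:
            cur = frontier.pop()
            for ch in network.channels:
                if (
                    ch.producer.kind == "process_port"
                    and ch.producer.process == cur
                    and ch.consumer.kind == "process_port"
                ):
                    d = ch.consumer.process
                    if d not in dependents:
                        dependents.add(d)
                        frontier.append(d)
        for d in dependents:
            proc = procs.get(d)
            if proc is not None and proc.poll() is None:
                store.try_set(d, 0, STOPPED)
                _kill_group(proc.pid, config.grace_period)

    def _watch(name: str, proc: subprocess.Popen) -> None:
        code = proc.wait()
        if code == 0:
            store.try_set(name, 0, COMPLETED, exit_code=0)
            executor.notify_done(name)
        elif launcher.stop_requested():
            store.try_set(name, 0, STOPPED, exit_code=code)
            executor.notify_failed(name)
        else:
            if store.try_set(name, 0, FAILED, exit_code=code):
                _kill_dependents(name)
            executor.notify_failed(name)

    try:
        # all FBP processes start before any job step
        spawn_failed: list[str] = []
        for name in fbp:
            if name in skipped:
                executor.notify_done(name)
                continue
            proc = launcher.spawn(name, 0)
            if proc is None:
                spawn_failed.append(name)
                continue
            procs[name] = proc
        for name, proc in procs.items():
            t = threading.Thread(target=_watch, args=(name, proc), daemon=True)
            t.start()
            watchers.append(t)
        for name in spawn_failed:
            _kill_dependents(name)
            executor.notify_failed(name)

        watchdog = None
        if network.cyclic and procs:
            watchdog = threading.Thread(
                target=_deadlock_watchdog,
                args=(network, tree, store, procs, config, activity),
                daemon=True,
            )
            watchdog.start()

        executor.run_to_completion()
        for t in watchers:
            t.join()
        activity.set()
        if watchdog is not None:
            watchdog.join(timeout=2)
        pool.drain(timeout=max(60.0, config.deadlock_timeout))
    finally:
        activity.set()
        pool.close()


def _kill_group(pid: int, grace: float) -> None:
    try:
        os.killpg(pid, signal.SIGTERM)
    except (ProcessLookupError, PermissionError):
        return
    deadline = time.monotonic() + grace
    while time.monotonic() < deadline:
        try:
            os.killpg(pid, 0)
        except ProcessLookupError:
            return
        time.sleep(0.05)
    try:
        os.killpg(pid, signal.SIGKILL)
    except (ProcessLookupError, PermissionError):
        pass


def _deadlock_watchdog(network, tree, store, procs, config, done_event) -> None:
    """Fail a cyclic run when nothing has moved for deadlock_timeout."""

    def _signature():
        sig = []
        for name in procs:
            for p in tree.process_dir(name).iterdir():
                try:
                    st = p.stat()
                    sig.append((str(p), st.st_size, st.st_mtime_ns))
                except OSError:
                    pass
        for f in tree.fifos_dir.iterdir():
            try:
                st = f.stat()
                sig.append((str(f), st.st_mtime_ns))
            except OSError:
                pass
        sig.append(tuple((n, p.poll()) for n, p in procs.items()))
        return tuple(sorted(map(repr, sig)))

    interval = max(config.deadlock_timeout / 4.0, 0.05)
    last_sig = _signature()
    last_change = time.monotonic()
    while not done_event.wait(interval):
        if all(p.poll() is not None for p in procs.values()):
            return
        sig = _signature()
        if sig != last_sig:
            last_sig = sig
            last_change = time.monotonic()
            continue
        if time.monotonic() - last_change >= config.deadlock_timeout:
            diagnosis = (
                "deadlock: cyclic network made no progress for "
                f"{config.deadlock_timeout:.1f}s; killed: "
                + ", ".join(sorted(procs))
            )
            (tree.exec_dir / "deadlock").write_text(diagnosis + "\n")
            # mark before killing so the exit watchers see terminal states
            for name, proc in procs.items():
                if proc.poll() is None:
                    store.try_set(name, 0, FAILED, exit_code=-1)
            for _name, proc in procs.items():
                if proc.poll() is None:
                    _kill_group(proc.pid, 0.5)
            return


def status(root: os.PathLike | str) -> list[ExecutionState]:
    """Read-only view of the last persisted transitions."""
    tree = OutputTree.attach(root)
    return StateStore(tree).states()


def stop(root: os.PathLike | str, grace: float = 2.0) -> RunReport:
    """Terminate all live process trees and persist ``stopped`` states.

    Best-effort and idempotent: already-finished processes are untouched,
    and stopping a finished run changes nothing.
    """
    tree = OutputTree.attach(root)
    # marker first: a live engine seeing its children die must record
    # "stopped", not "failed"
    (tree.exec_dir / "stop").touch()
    store = StateStore(tree)
    for st in store.states():
        if st.status in (PENDING, IN_PROGRESS):
            store.try_set(st.process, st.task_index, STOPPED)
    pids_file = tree.exec_dir / "pids"
    if pids_file.exists():
        for line in pids_file.read_text().splitlines():
            parts = line.split("\t")
            if not parts:
                continue
            try:
                _kill_group(int(parts[0]), grace)
            except ValueError:
                continue
    # clean pipes so external readers/writers unblock on stale channels
    if tree.fifos_dir.is_dir():
        for f in list(tree.fifos_dir.iterdir()):
            try:
                f.unlink()
            except OSError:
                pass
    states = store.states()
    return RunReport(
        root=Path(root), final_states=tuple(states), overall=_overall(states)
    )


# ---------------------------------------------------------------------------
# Imperative invocation
# ---------------------------------------------------------------------------


def invoke_inline(
    network: ResolvedNetwork,
    process: str,
    args: Sequence[str],
    cwd: os.PathLike | str | None = None,
) -> tuple[int, bytes]:
    """Run one process body synchronously with explicit option bindings.

    Bypasses schedulers and channels and records no execution state —
    imperative calls are the caller's responsibility.  Returns
    ``(exit_code, captured_stdout)``.
    """
    spec = network.program.process(process)
    for port in spec.ports:
        if port.direction == INPUT and port.required:
            if read_opt_value(args, port.option_token) is NOT_FOUND:
                raise UnboundInputError(
                    f"imperative call to {process}: required option "
                    f"{port.option_token!r} not provided"
                )
    if spec.body.form == "native_callable":
        import io

        out, err = io.StringIO(), io.StringIO()
        try:
            code = spec.body.fn(list(args), out, err)
            code = 0 if code is None else int(code)
        except Exception as exc:
            err.write(f"{type(exc).__name__}: {exc}\n")
            code = 1
        return code, out.getvalue().encode()
    if spec.body.form == "command_text":
        cmd = ["bash", "-c", spec.body.text, process, *args]
    else:
        import tempfile

        with tempfile.NamedTemporaryFile(
            "w", suffix=".script", delete=False
        ) as fh:
            fh.write(spec.body.text)
            script = fh.name
        cmd = [_interpreter_command(spec.body.interpreter), script, *args]
    result = subprocess.run(cmd, capture_output=True, cwd=cwd)
    return result.returncode, result.stdout
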