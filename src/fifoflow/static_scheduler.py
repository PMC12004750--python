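"""Static scheduling: compile the dependency graph into a minimal
submission plan (one array job per process template) and push it through a
batch backend in a single pass.

The point of the static mode is scalability: the number of submissions
depends only on the number of process templates, never on array sizes, and
after :func:`submit_all` returns the engine does no scheduling work at all —
it just waits for completion callbacks.
"""

from __future__ import annotations

import random
import threading
from dataclasses import dataclass
from typing import Callable, Iterable, Protocol, Sequence

import networkx as nx

from .errors import BackendError, SchedulerError
from .network_resolution import ResolvedNetwork
from .program_model import Resources

__all__ = [
    "PlannedJob",
    "SubmissionPlan",
    "LocalCapacity",
    "BatchBackend",
    "MockBackend",
    "LocalBackend",
    "build_plan",
    "submit_all",
    "allocate_local",
    "dump_plan",
    "load_plan_text",
]

AFTEROK = "afterok"

PLAN_HEADER = "# fifoflow plan v1"


@dataclass(frozen=True)
class PlannedJob:
    job_key: str  # process name
    array_size: int
    resources: Resources
    depends_on: tuple[str, ...] = ()
    dependency_type: str = AFTEROK


@dataclass(frozen=True)
class SubmissionPlan:
    jobs: tuple[PlannedJob, ...]

    def job(self, key: str) -> PlannedJob:
        for j in self.jobs:
            if j.job_key == key:
                return j
        raise KeyError(key)


@dataclass(frozen=True)
class LocalCapacity:
    cpus: int
    mem_mb: int


def build_plan(network: ResolvedNetwork) -> SubmissionPlan:
    """One array job per job-step process, in topological order with
    declaration order as the deterministic tie-break."""
    fbp = network.fbp_processes()
    if fbp:
        raise SchedulerError(
            "static scheduling covers job steps only; FBP processes present: "
            + ", ".join(fbp)
        )
    decl = {name: i for i, name in enumerate(network.program.process_names)}
    g = network.dependency_graph
    order = list(nx.lexicographical_topological_sort(g, key=lambda n: decl[n]))
    jobs = []
    for name in order:
        spec = network.program.process(name)
        deps = sorted(g.predecessors(name), key=decl.__getitem__)
        jobs.append(
            PlannedJob(
                job_key=name,
                array_size=network.task_counts[name],
                resources=spec.resources,
                depends_on=tuple(deps),
            )
        )
    return SubmissionPlan(jobs=tuple(jobs))


def dump_plan(plan: SubmissionPlan) -> str:
    lines = [PLAN_HEADER]
    for j in plan.jobs:
        after = ",".join(j.depends_on) if j.depends_on else "-"
        lines.append(
            f"job\t{j.job_key}\tarray={j.array_size}\tcpus={j.resources.cpus}"
            f"\tmem_mb={j.resources.mem_mb}\ttime_min={j.resources.time_min}"
            f"\t{j.dependency_type}={after}"
        )
    return "\n".join(lines) + "\n"


def load_plan_text(text: str) -> SubmissionPlan:
    lines = text.strip().splitlines()
    if not lines or lines[0] != PLAN_HEADER:
        raise SchedulerError("not a fifoflow plan file")
    jobs = []
    for line in lines[1:]:
        parts = line.split("\t")
        fields = dict(p.split("=", 1) for p in parts[2:])
        dep_type, after = parts[-1].split("=", 1)
        jobs.append(
            PlannedJob(
                job_key=parts[1],
                array_size=int(fields["array"]),
                resources=Resources(
                    cpus=int(fields["cpus"]),
                    mem_mb=int(fields["mem_mb"]),
                    time_min=int(fields["time_min"]),
                ),
                depends_on=tuple(after.split(",")) if after != "-" else (),
                dependency_type=dep_type,
            )
        )
    return SubmissionPlan(jobs=tuple(jobs))


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


class BatchBackend(Protocol):
    """Plug-in contract for batch submission backends.

    ``submit`` receives the job plus the backend ids of its prerequisites
    (already resolved — this is the whole point of static scheduling) and
    returns an opaque id.  ``poll`` must be side-effect-free.  Backends call
    the registered completion callback once per finished job, so the engine
    can sleep in between.
    """

    def submit(self, job: PlannedJob, depends_on_ids: Sequence[str]) -> str: ...

    def cancel(self, backend_id: str) -> None: ...

    def poll(self, backend_id: str) -> str: ...

    def on_complete(self, fn: Callable[[str, str], None]) -> None: ...

    def run_to_completion(self) -> None: ...


def submit_all(plan: SubmissionPlan, backend: BatchBackend) -> dict[str, str]:
    """Submit every job in one pass, dependencies pre-resolved to backend ids.

    On a backend rejection the already-submitted jobs are cancelled and the
    error re-raised; nothing is retried here.
    """
    ids: dict[str, str] = {}
    for job in plan.jobs:
        dep_ids = [ids[d] for d in job.depends_on]
        try:
            ids[job.job_key] = backend.submit(job, dep_ids)
        except BackendError:
            for done_key in reversed(list(ids)):
                backend.cancel(ids[done_key])
            raise
    return ids


class MockBackend:
    """Recording backend for tests and acceptance runs.

    Every engine-initiated call (submit/cancel/poll) is appended to
    ``calls`` — the quiescence assertion surface.  ``run_to_completion``
    simulates the external scheduler: it finishes jobs in a randomized
    order that respects afterok edges, optionally invoking *task_runner*
    for each array task (used by sentinel-file dependency tests).
    """

    def __init__(
        self,
        seed: int | None = None,
        reject_job_keys: Iterable[str] = (),
        task_runner: Callable[[PlannedJob, int], None] | None = None,
    ):
        self.calls: list[tuple] = []
        self._rng = random.Random(seed)
        self._reject = set(reject_job_keys)
        self._task_runner = task_runner
        self._jobs: dict[str, PlannedJob] = {}
        self._deps: dict[str, tuple[str, ...]] = {}
        self._state: dict[str, str] = {}
        self._next = 1
        self._callback: Callable[[str, str], None] | None = None

    @property
    def submit_calls(self) -> list[tuple]:
        return [c for c in self.calls if c[0] == "submit"]

    def on_complete(self, fn: Callable[[str, str], None]) -> None:
        self._callback = fn

    def submit(self, job: PlannedJob, depends_on_ids: Sequence[str]) -> str:
        self.calls.append(("submit", job.job_key, tuple(depends_on_ids)))
        if job.job_key in self._reject:
            raise BackendError(f"backend rejected job {job.job_key!r}")
        backend_id = str(self._next)
        self._next += 1
        self._jobs[backend_id] = job
        self._deps[backend_id] = tuple(depends_on_ids)
        self._state[backend_id] = "queued"
        return backend_id

    def cancel(self, backend_id: str) -> None:
        self.calls.append(("cancel", backend_id))
        if self._state.get(backend_id) in ("queued", "running"):
            self._state[backend_id] = "cancelled"

    def poll(self, backend_id: str) -> str:
        self.calls.append(("poll", backend_id))
        return self._state[backend_id]

    def run_to_completion(self) -> None:
        done: set[str] = set()
        pending = [i for i, s in self._state.items() if s == "queued"]
        while pending:
            eligible = [
                i for i in pending if all(d in done for d in self._deps[i])
            ]
            if not eligible:
                raise BackendError("mock backend: unsatisfiable dependencies")
            chosen = self._rng.choice(eligible)
            pending.remove(chosen)
            job = self._jobs[chosen]
            self._state[chosen] = "running"
            if self._task_runner is not None:
                for task in range(job.array_size):
                    self._task_runner(job, task)
            self._state[chosen] = "done"
            done.add(chosen)
            if self._callback is not None:
                self._callback(chosen, "done")


# ---------------------------------------------------------------------------
# Local allocation (the knapsack-style built-in scheduler)
# ---------------------------------------------------------------------------


def allocate_local(
    pending: Sequence[Resources], capacity: LocalCapacity
) -> list[int]:
    """Select a feasible, maximal-under-first-fit subset of *pending*.

    Greedy by input order with first-fit on (cpus, mem_mb): deterministic,
    never exceeds capacity, and maximal in the sense that no skipped task
    would have fit at the moment it was considered.
    """
    chosen: list[int] = []
    cpus_left, mem_left = capacity.cpus, capacity.mem_mb
    for i, r in enumerate(pending):
        if r.cpus <= cpus_left and r.mem_mb <= mem_left:
            chosen.append(i)
            cpus_left -= r.cpus
            mem_left -= r.mem_mb
    return chosen


class LocalBackend:
    """Built-in executor honoring afterok dependencies and a 2-D capacity.

    *run_task* is supplied by the engine: it launches one array task and
    returns its exit code.  The backend decides only *when* tasks start.
    """

    def __init__(
        self,
        capacity: LocalCapacity,
        run_task: Callable[[str, int], int],
        cancel_task: Callable[[str, int], None] | None = None,
    ):
        self.capacity = capacity
        self._run_task = run_task
        self._cancel_task = cancel_task
        self._jobs: dict[str, PlannedJob] = {}
        self._deps: dict[str, tuple[str, ...]] = {}
        self._state: dict[str, str] = {}
        self._next = 1
        self._callback: Callable[[str, str], None] | None = None

    def on_complete(self, fn: Callable[[str, str], None]) -> None:
        self._callback = fn

    def submit(self, job: PlannedJob, depends_on_ids: Sequence[str]) -> str:
        if job.resources.cpus > self.capacity.cpus or (
            job.resources.mem_mb > self.capacity.mem_mb
        ):
            raise BackendError(
                f"job {job.job_key!r} demands more than total capacity"
            )
        backend_id = str(self._next)
        self._next += 1
        self._jobs[backend_id] = job
        self._deps[backend_id] = tuple(depends_on_ids)
        self._state[backend_id] = "queued"
        return backend_id

    def cancel(self, backend_id: str) -> None:
        if self._state.get(backend_id) == "queued":
            self._state[backend_id] = "cancelled"

    def poll(self, backend_id: str) -> str:
        return self._state[backend_id]

    def run_to_completion(self) -> None:
        cond = threading.Condition()
        cpus_used = 0
        mem_used = 0
        in_flight = 0
        started: set[tuple[str, int]] = set()
        finished: dict[str, int] = {i: 0 for i in self._jobs}  # finished tasks
        failed: set[str] = set()
        done: set[str] = set()

        def _eligible(backend_id: str) -> bool:
            if self._state[backend_id] != "queued":
                return False
            return all(d in done for d in self._deps[backend_id])

        def _cancel_downstream() -> None:
            changed = True
            while changed:
                changed = False
                for i in self._jobs:
                    if self._state[i] != "queued":
                        continue
                    if any(
                        self._state.get(d) in ("failed", "cancelled")
                        for d in self._deps[i]
                    ):
                        self._state[i] = "cancelled"
                        changed = True
                        if self._cancel_task is not None:
                            for t in range(self._jobs[i].array_size):
                                self._cancel_task(self._jobs[i].job_key, t)
                        if self._callback is not None:
                            self._callback(i, "cancelled")

        def _worker(backend_id: str, task: int) -> None:
            nonlocal cpus_used, mem_used, in_flight
            job = self._jobs[backend_id]
            code = self._run_task(job.job_key, task)
            with cond:
                cpus_used -= job.resources.cpus
                mem_used -= job.resources.mem_mb
                in_flight -= 1
                finished[backend_id] += 1
                if code != 0:
                    failed.add(backend_id)
                if finished[backend_id] == job.array_size:
                    if backend_id in failed:
                        self._state[backend_id] = "failed"
                    else:
                        self._state[backend_id] = "done"
                        done.add(backend_id)
                    if self._callback is not None:
                        self._callback(backend_id, self._state[backend_id])
                cond.notify_all()

        with cond:
            while True:
                _cancel_downstream()
                if all(
                    self._state[i] in ("done", "failed", "cancelled")
                    for i in self._jobs
                ):
                    break
                # gather runnable array tasks from eligible jobs, in order
                runnable: list[tuple[str, int]] = []
                for i in self._jobs:
                    if self._state[i] == "queued" and _eligible(i):
                        pass
                    elif self._state[i] != "running":
                        continue
                    for t in range(self._jobs[i].array_size):
                        if (i, t) not in started:
                            runnable.append((i, t))
                sel = allocate_local(
                    [self._jobs[i].resources for i, _t in runnable],
                    LocalCapacity(
                        self.capacity.cpus - cpus_used,
                        self.capacity.mem_mb - mem_used,
                    ),
                )
                for k in sel:
                    i, t = runnable[k]
                    job = self._jobs[i]
                    started.add((i, t))
                    self._state[i] = "running"
                    cpus_used += job.resources.cpus
                    mem_used += job.resources.mem_mb
                    in_flight += 1
                    threading.Thread(
                        target=_worker, args=(i, t), daemon=True
                    ).start()
                if sel:
                    continue
                if in_flight > 0:
                    cond.wait()
                    continue
                # nothing running and nothing fits: remaining queued jobs can
                # never be placed (submit() rejects over-capacity jobs, so
                # this only covers pathological capacities)
                for i in self._jobs:
                    if self._state[i] == "queued":
                        self._state[i] = "failed"
                        if self._callback is not None:
                            self._callback(i, "failed")
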