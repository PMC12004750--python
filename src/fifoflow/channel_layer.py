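"""Materialize channels on disk and expose FIFOs for external access.

The output tree layout is fixed::

    <root>/
      <process_name>/      one directory per process (stdout/stderr, files)
      __exec__/            execution state, logs, plan
      __fifos__/           one named pipe per stream channel
      __graphs__/          DOT exports

Every named pipe is created **before** any process is spawned, which is
what makes open-for-read/open-for-write rendezvous race-free.  Records are
newline-delimited bytes; end-of-stream is the OS pipe EOF (all writers
closed) — there are no in-band sentinels.
"""

from __future__ import annotations

import os
import stat
import threading
from dataclasses import dataclass
from pathlib import Path

from .errors import DuplicateNameError, ExecutionError, NotAnOutputTreeError
from .network_resolution import ResolvedNetwork

__all__ = ["OutputTree", "materialize", "open_external", "bridge", "BridgeHandle"]

EXEC_DIR = "__exec__"
FIFOS_DIR = "__fifos__"
GRAPHS_DIR = "__graphs__"
COMPUTATIONS_DIR = "__computations__"

_RESERVED = {EXEC_DIR, FIFOS_DIR, GRAPHS_DIR, COMPUTATIONS_DIR}

FIFO_MODE = 0o600  # owner-only; overridable through materialize()


@dataclass(frozen=True)
class OutputTree:
    """Paths of a materialized program output directory."""

    root: Path
    process_names: tuple[str, ...] = ()

    @property
    def exec_dir(self) -> Path:
        return self.root / EXEC_DIR

    @property
    def fifos_dir(self) -> Path:
        return self.root / FIFOS_DIR

    @property
    def graphs_dir(self) -> Path:
        return self.root / GRAPHS_DIR

    @property
    def computations_dir(self) -> Path:
        return self.root / COMPUTATIONS_DIR

    def process_dir(self, name: str) -> Path:
        return self.root / name

    def fifo_path(self, basename: str) -> Path:
        return self.fifos_dir / basename

    def list_fifos(self) -> list[str]:
        if not self.fifos_dir.is_dir():
            return []
        return sorted(
            p.name for p in self.fifos_dir.iterdir() if p.is_fifo()
        )

    @classmethod
    def attach(cls, root: os.PathLike | str) -> "OutputTree":
        """Attach to an existing tree (for status/stop tooling)."""
        root = Path(root)
        if not (root / EXEC_DIR).is_dir():
            raise NotAnOutputTreeError(
                f"{root} is not a program output directory (no {EXEC_DIR}/)"
            )
        names = tuple(
            sorted(
                p.name
                for p in root.iterdir()
                if p.is_dir() and p.name not in _RESERVED
            )
        )
        return cls(root=root, process_names=names)


def materialize(
    network: ResolvedNetwork, root: os.PathLike | str, fifo_mode: int = FIFO_MODE
) -> OutputTree:
    """Create the output tree and every stream channel's named pipe.

    Idempotent over an existing tree from an identical network; stale pipes
    are removed and recreated so a re-execution starts from clean channels.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if not os.access(root, os.W_OK):
        raise ExecutionError(f"output root {root} is not writable")
    names = tuple(network.program.process_names)
    for name in names:
        if name in _RESERVED:
            raise DuplicateNameError(f"process name {name!r} is reserved")
        (root / name).mkdir(exist_ok=True)
    tree = OutputTree(root=root, process_names=names)
    tree.exec_dir.mkdir(exist_ok=True)
    tree.graphs_dir.mkdir(exist_ok=True)
    tree.fifos_dir.mkdir(exist_ok=True)

    wanted: dict[str, None] = {}
    for ch in network.stream_channels():
        if ch.fifo_basename in wanted:
            raise DuplicateNameError(
                f"FIFO basename collision on disk: {ch.fifo_basename!r}"
            )
        wanted[ch.fifo_basename] = None

    # drop stale pipes from earlier runs/other networks, then (re)create
    for entry in tree.fifos_dir.iterdir():
        entry.unlink()
    for basename in wanted:
        path = tree.fifo_path(basename)
        os.mkfifo(path, mode=fifo_mode)
    return tree


def open_external(root: os.PathLike | str, fifo_basename: str, mode: str = "read"):
    """Open an exposed FIFO from outside the program.

    Honors OS pipe semantics: opening for read blocks until a writer
    exists and vice versa (use ``os.open`` with ``O_NONBLOCK`` directly for
    non-blocking probes).  Returns a buffered file object.
    """
    tree = OutputTree.attach(root)
    path = tree.fifo_path(fifo_basename)
    if not path.exists() or not stat.S_ISFIFO(path.stat().st_mode):
        available = ", ".join(tree.list_fifos()) or "(none)"
        raise ExecutionError(
            f"no FIFO named {fifo_basename!r}; available pipes: {available}"
        )
    if mode == "read":
        return open(path, "rb")
    if mode == "write":
        return open(path, "wb")
    raise ExecutionError(f"mode must be 'read' or 'write', got {mode!r}")


@dataclass
class BridgeHandle:
    """A running relay between two exposed FIFOs of independent programs."""

    thread: threading.Thread
    _stop: threading.Event
    records_copied: int = 0
    error: BaseException | None = None

    def join(self, timeout: float | None = None) -> None:
        self.thread.join(timeout)

    def stop(self) -> None:
        self._stop.set()
        self.thread.join(timeout=5)

    @property
    def alive(self) -> bool:
        return self.thread.is_alive()


def bridge(
    root_a: os.PathLike | str,
    fifo_out: str,
    root_b: os.PathLike | str,
    fifo_in: str,
    record_sink=None,
) -> BridgeHandle:
    """Relay records from *fifo_out* (producer side of program A) into
    *fifo_in* (consumer side of program B) until end-of-stream, then
    propagate EOF by closing the write end.

    *record_sink*, if given, receives each relayed record (bytes, without
    terminator) — used by instrumented stream-conservation tests.
    """
    tree_a = OutputTree.attach(root_a)
    tree_b = OutputTree.attach(root_b)
    for tree, name in ((tree_a, fifo_out), (tree_b, fifo_in)):
        p = tree.fifo_path(name)
        if not p.exists():
            available = ", ".join(tree.list_fifos()) or "(none)"
            raise ExecutionError(
                f"no FIFO named {name!r} under {tree.root}; available: {available}"
            )

    stop = threading.Event()
    handle = BridgeHandle(thread=None, _stop=stop)  # type: ignore[arg-type]

    def _run() -> None:
        try:
            with open(tree_a.fifo_path(fifo_out), "rb") as src:
                with open(tree_b.fifo_path(fifo_in), "wb") as dst:
                    for line in src:
                        if stop.is_set():
                            break
                        dst.write(line)
                        dst.flush()
                        handle.records_copied += 1
                        if record_sink is not None:
                            record_sink(line.rstrip(b"\n"))
        except BaseException as exc:  # surfaced on the handle, not lost
            handle.error = exc

    t = threading.Thread(target=_run, name=f"bridge:{fifo_out}->{fifo_in}", daemon=True)
    handle.thread = t
    t.start()
    return handle
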