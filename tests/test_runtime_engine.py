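import os
import signal
import time

import pytest

from fifoflow import (
    BodySpec,
    CmdlineOpt,
    FromProcessOut,
    OutFile,
    PortSpec,
    ProcessSpec,
    ProgramSpec,
    EngineConfig,
    execute,
    invoke_inline,
    materialize,
    resolve,
    status,
    stop,
)
from fifoflow.channel_layer import OutputTree
from fifoflow.errors import NotAnOutputTreeError, UnboundInputError
from fifoflow.examples import (
    build_counter,
    build_telegram,
    build_telegram_steps,
    decompose,
    telegram_reflow,
)
from fifoflow.runtime_engine import (
    COMPLETED,
    FAILED,
    IN_PROGRESS,
    LEGAL_TRANSITIONS,
    PENDING,
    STOPPED,
    StateStore,
)


def _sleepy_chain(sleep_s=2.0):
    """Job-step chain a -> b where a sleeps before writing its output."""
    program = ProgramSpec("chain")
    program.register_process(
        ProcessSpec(
            name="a",
            body=BodySpec.command(
                'outf=""; while [ $# -gt 0 ]; do case "$1" in -outf) outf="$2"; shift 2;; *) shift;; esac; done; '
                f"sleep {sleep_s}; echo done > \"$outf\""
            ),
            ports=(PortSpec("-outf", payload="path"),),
            connect=(OutFile("-outf", "a.txt"),),
        )
    )
    program.register_process(
        ProcessSpec(
            name="b",
            body=BodySpec.command(
                'inf=""; outf=""; while [ $# -gt 0 ]; do case "$1" in -inf) inf="$2"; shift 2;; -outf) outf="$2"; shift 2;; *) shift;; esac; done; '
                'cat "$inf" > "$outf"'
            ),
            ports=(
                PortSpec("-inf", payload="path"),
                PortSpec("-outf", payload="path"),
            ),
            connect=(
                FromProcessOut("-inf", "a", "-outf"),
                OutFile("-outf", "b.txt"),
            ),
        )
    )
    return program


TELEGRAM_TEXT = "some words to reflow into short lines please\n"


class TestExecute:
    def test_telegram_all_completed(self, tmp_path, patient_config):
        src = tmp_path / "in.txt"
        src.write_text(TELEGRAM_TEXT)
        net = resolve(build_telegram(), ["-f", str(src), "-l", "12"])
        report = execute(net, tmp_path / "out", config=patient_config)
        assert report.overall == "completed"
        assert {s.process for s in report.final_states} == {
            "rseq", "decomposer", "recomposer", "wseq",
        }
        assert all(s.status == COMPLETED for s in report.final_states)
        assert (tmp_path / "out" / "wseq" / "output.txt").exists()
        for d in ("__exec__", "__fifos__", "__graphs__"):
            assert (tmp_path / "out" / d).is_dir()

    def test_empty_program_completes_with_no_states(self, tmp_path):
        report = execute(resolve(ProgramSpec("empty")), tmp_path / "out")
        assert report.overall == "completed"
        assert report.final_states == ()

    def test_spawn_failure_cancels_dependents(self, tmp_path, patient_config):
        program = ProgramSpec("m")
        program.register_process(
            ProcessSpec(
                name="bad",
                body=BodySpec.script("whatever", "no_such_interpreter_xyz"),
                ports=(PortSpec("-out", payload="stream"),),
                connect=(),
            )
        )
        program.register_process(
            ProcessSpec(
                name="reader",
                body=BodySpec.script(
                    "import sys\nopen(sys.argv[2]).read()\n", "python"
                ),
                ports=(PortSpec("-in", payload="stream"),),
                connect=(FromProcessOut("-in", "bad", "-out"),),
            )
        )
        report = execute(resolve(program), tmp_path / "out", config=patient_config)
        by_name = {s.process: s.status for s in report.final_states}
        assert by_name["bad"] == FAILED
        assert by_name["reader"] == STOPPED
        assert report.overall in ("failed", "stopped")


class TestStatus:
    def test_mid_run_shows_in_progress(self, tmp_path, run_async, patient_config):
        net = resolve(_sleepy_chain(1.0))
        run = run_async(net, tmp_path / "out", config=patient_config)
        time.sleep(0.4)
        states = status(tmp_path / "out")
        assert any(s.status == IN_PROGRESS for s in states)
        run.join()

    def test_after_success_all_completed(self, tmp_path, patient_config):
        net = resolve(_sleepy_chain(0.0))
        execute(net, tmp_path / "out", config=patient_config)
        assert all(s.status == COMPLETED for s in status(tmp_path / "out"))

    def test_non_tree_rejected(self, tmp_path):
        with pytest.raises(NotAnOutputTreeError):
            status(tmp_path)

    def test_fresh_tree_before_launch_all_pending(self, tmp_path):
        net = resolve(_sleepy_chain(0.0))
        tree = materialize(net, tmp_path / "out")
        store = StateStore(tree)
        for name in net.program.process_names:
            store.init_pending(name, 1)
        assert all(s.status == PENDING for s in status(tmp_path / "out"))


class TestFaultInjection:
    def test_kill9_marks_failed_and_stops_dependents(
        self, tmp_path, run_async, patient_config
    ):
        net = resolve(_sleepy_chain(5.0))
        run = run_async(net, tmp_path / "out", config=patient_config)
        pids_file = tmp_path / "out" / "__exec__" / "pids"
        deadline = time.monotonic() + 5
        pid = None
        while time.monotonic() < deadline and pid is None:
            if pids_file.exists():
                for line in pids_file.read_text().splitlines():
                    fields = line.split("\t")
                    if fields[1] == "a":
                        pid = int(fields[0])
            time.sleep(0.05)
        assert pid is not None
        os.killpg(pid, signal.SIGKILL)
        report = run.join()
        by_name = {s.process: s.status for s in report.final_states}
        assert by_name["a"] == FAILED
        assert by_name["b"] == STOPPED

    def test_transitions_stay_legal_after_kill(
        self, tmp_path, run_async, patient_config
    ):
        net = resolve(_sleepy_chain(5.0))
        run = run_async(net, tmp_path / "out", config=patient_config)
        time.sleep(0.5)
        pids_file = tmp_path / "out" / "__exec__" / "pids"
        for line in pids_file.read_text().splitlines():
            try:
                os.killpg(int(line.split("\t")[0]), signal.SIGKILL)
            except ProcessLookupError:
                pass
        run.join()
        store = StateStore(OutputTree.attach(tmp_path / "out"))
        for process in ("a", "b"):
            last = {}
            for task, st, _code, _ts, reset in store.history(process):
                if reset or task not in last:
                    last[task] = st
                    continue
                assert st in LEGAL_TRANSITIONS[last[task]], (
                    f"illegal {last[task]} -> {st} for {process}[{task}]"
                )
                last[task] = st


class TestStop:
    def test_stop_during_infinite_counter(self, tmp_path, run_async, patient_config):
        # nobody reads counter_out, so the counter blocks on open() forever
        net = resolve(build_counter(), ["-inn", "1000000"])
        run = run_async(net, tmp_path / "out", config=patient_config)
        time.sleep(0.5)
        report = stop(tmp_path / "out")
        assert report.overall == "stopped"
        run.join()
        assert OutputTree.attach(tmp_path / "out").list_fifos() == []

    def test_stop_after_completion_is_noop(self, tmp_path, patient_config):
        net = resolve(_sleepy_chain(0.0))
        execute(net, tmp_path / "out", config=patient_config)
        before = [(s.process, s.status) for s in status(tmp_path / "out")]
        report = stop(tmp_path / "out")
        assert report.overall == "completed"
        assert [(s.process, s.status) for s in report.final_states] == before

    def test_double_stop_identical(self, tmp_path, run_async, patient_config):
        net = resolve(build_counter(), ["-inn", "1000000"])
        run = run_async(net, tmp_path / "out", config=patient_config)
        time.sleep(0.5)
        first = stop(tmp_path / "out")
        second = stop(tmp_path / "out")
        assert [s.status for s in first.final_states] == [
            s.status for s in second.final_states
        ]
        run.join()


class TestResume:
    def test_rerun_performs_no_work(self, tmp_path, patient_config):
        src = tmp_path / "in.txt"
        src.write_text(TELEGRAM_TEXT)
        net = resolve(build_telegram_steps(), ["-f", str(src), "-l", "12"])
        execute(net, tmp_path / "out", config=patient_config)
        out = tmp_path / "out" / "wseq" / "output.txt"
        first_mtime = out.stat().st_mtime_ns
        report = execute(net, tmp_path / "out", config=patient_config)
        assert report.overall == "completed"
        assert out.stat().st_mtime_ns == first_mtime  # body not re-run

    def test_changed_options_reset_and_rerun(self, tmp_path, patient_config):
        src = tmp_path / "in.txt"
        src.write_text(TELEGRAM_TEXT)
        net = resolve(build_telegram_steps(), ["-f", str(src), "-l", "12"])
        execute(net, tmp_path / "out", config=patient_config)
        out = tmp_path / "out" / "wseq" / "output.txt"
        first = out.read_text()
        net2 = resolve(build_telegram_steps(), ["-f", str(src), "-l", "30"])
        report = execute(net2, tmp_path / "out", config=patient_config)
        assert report.overall == "completed"
        assert out.read_text() != first


class TestDeadlockWatchdog:
    def test_cyclic_standstill_is_diagnosed(self, tmp_path):
        # both processes open their input first: classic rendezvous deadlock
        body = (
            "import sys\n"
            "def opt(t):\n"
            "    a = sys.argv[1:]\n"
            "    for i in range(len(a) - 1):\n"
            "        if a[i] == t:\n"
            "            return a[i + 1]\n"
            "r = open(opt('-in'))\n"
            "w = open(opt('-out'), 'w')\n"
        )
        program = ProgramSpec("dead")
        for name, other in (("p1", "p2"), ("p2", "p1")):
            program.register_process(
                ProcessSpec(
                    name=name,
                    body=BodySpec.script(body, "python"),
                    ports=(
                        PortSpec("-in", payload="stream"),
                        PortSpec("-out", payload="stream"),
                    ),
                    connect=(FromProcessOut("-in", other, "-out"),),
                )
            )
        net = resolve(program)
        assert net.cyclic
        config = EngineConfig(deadlock_timeout=1.5)
        report = execute(net, tmp_path / "out", config=config)
        assert report.overall == "failed"
        diagnosis = (tmp_path / "out" / "__exec__" / "deadlock").read_text()
        assert "deadlock" in diagnosis


class TestStateStore:
    def test_illegal_transition_raises(self, tmp_path):
        net = resolve(ProgramSpec("empty"))
        tree = materialize(net, tmp_path / "out")
        store = StateStore(tree)
        store.set("p", 0, PENDING)
        with pytest.raises(Exception):
            store.set("p", 0, COMPLETED)  # must pass through in_progress

    def test_same_status_is_idempotent_noop(self, tmp_path):
        tree = materialize(resolve(ProgramSpec("empty")), tmp_path / "out")
        store = StateStore(tree)
        store.set("p", 0, PENDING)
        store.set("p", 0, STOPPED)
        assert store.try_set("p", 0, STOPPED)
        assert len(store.history("p")) == 2  # the no-op was not logged

    def test_recovery_from_disk(self, tmp_path):
        tree = materialize(resolve(ProgramSpec("empty")), tmp_path / "out")
        store = StateStore(tree)
        store.set("p", 0, PENDING)
        store.set("p", 0, IN_PROGRESS)
        store.set("p", 0, COMPLETED, exit_code=0)
        reloaded = StateStore(tree)
        (st,) = reloaded.states()
        assert st.status == COMPLETED and st.exit_code == 0
        assert st.start_time is not None and st.end_time is not None


class TestInvokeInline:
    def test_stream_echo_on_regular_file(self, tmp_path, patient_config):
        from fifoflow.examples import build_stream_echo

        src = tmp_path / "data.txt"
        src.write_text("alpha\nbeta\n")
        net = resolve(build_stream_echo(), [])
        code, out = invoke_inline(net, "stream_echo", ["-in", str(src)])
        assert code == 0
        assert out == b"alpha\nbeta\n"

    def test_missing_required_option_names_it(self, tmp_path):
        net = resolve(build_telegram(), ["-f", "/tmp/x", "-l", "10"])
        with pytest.raises(UnboundInputError) as exc:
            invoke_inline(net, "decomposer", ["-outf", str(tmp_path / "o")])
        assert "-inf" in str(exc.value)

    def test_imperative_telegram_equals_network_run(self, tmp_path, patient_config):
        src = tmp_path / "in.txt"
        src.write_text(TELEGRAM_TEXT)
        net = resolve(build_telegram(), ["-f", str(src), "-l", "12"])
        report = execute(net, tmp_path / "net", config=patient_config)
        assert report.overall == "completed"
        network_out = (tmp_path / "net" / "wseq" / "output.txt").read_bytes()

        t1, t2, t3, final = (tmp_path / f"s{i}" for i in range(4))
        for process, args in (
            ("rseq", ["-f", str(src), "-outf", str(t1)]),
            ("decomposer", ["-inf", str(t1), "-outf", str(t2)]),
            ("recomposer", ["-inf", str(t2), "-l", "12", "-outf", str(t3)]),
            ("wseq", ["-inf", str(t3), "-outf", str(final)]),
        ):
            code, _ = invoke_inline(net, process, args)
            assert code == 0
        assert final.read_bytes() == network_out
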