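import itertools
import random

import networkx as nx
import pytest

from fifoflow import (
    BodySpec,
    CmdlineOpt,
    FifoOpt,
    FromProcessOut,
    OutFile,
    PortSpec,
    ProcessSpec,
    ProgramSpec,
    ValueOpt,
    build_dependency_graph,
    export_graph,
    resolve,
)
from fifoflow.errors import (
    DefinitionError,
    DirectionMismatchError,
    DuplicateNameError,
    PortAlreadyBoundError,
    UnboundInputError,
    UnknownOptionError,
    UnknownProcessError,
)
from fifoflow.examples import (
    build_counter,
    build_host_workflow,
    build_master_worker,
    build_master_worker_triggered,
    build_stream_echo,
    build_telegram,
)

TELEGRAM_ARGS = ["-f", "/tmp/in.txt", "-l", "20"]
MW_ARGS = ["-invalue", "0", "-inn", "10", "-inthreshold", "5"]


def _step(name, out_token="-outf", in_from=None):
    """A job-step process writing one file, optionally consuming another."""
    ports = [PortSpec(out_token, payload="path")]
    connect = [OutFile(out_token, f"{name}.txt")]
    if in_from is not None:
        ports.insert(0, PortSpec("-inf", payload="path"))
        connect.insert(0, FromProcessOut("-inf", in_from, "-outf"))
    return ProcessSpec(
        name=name,
        body=BodySpec.command("true"),
        ports=tuple(ports),
        connect=tuple(connect),
    )


def _diamond():
    program = ProgramSpec("diamond")
    for spec in (
        _step("a"),
        _step("b", in_from="a"),
        _step("c", in_from="a"),
        ProcessSpec(
            name="d",
            body=BodySpec.command("true"),
            ports=(
                PortSpec("-inb", payload="path"),
                PortSpec("-inc", payload="path"),
                PortSpec("-outf", payload="path"),
            ),
            connect=(
                FromProcessOut("-inb", "b", "-outf"),
                FromProcessOut("-inc", "c", "-outf"),
                OutFile("-outf", "d.txt"),
            ),
        ),
    ):
        program.register_process(spec)
    return program


class TestResolveTelegram:
    def test_structure(self):
        net = resolve(build_telegram(), TELEGRAM_ARGS)
        assert len(net.program.processes) == 4
        streams = net.stream_channels()
        assert len(streams) == 3
        chain = [
            (c.producer.process, c.consumer.process) for c in streams
        ]
        assert chain == [
            ("rseq", "decomposer"),
            ("decomposer", "recomposer"),
            ("recomposer", "wseq"),
        ]
        assert net.cyclic is False

    def test_missing_required_option_names_port(self):
        with pytest.raises(UnboundInputError) as exc:
            resolve(build_telegram(), ["-l", "20"])
        assert "rseq" in str(exc.value) and "-f" in str(exc.value)

    def test_unknown_cmdline_token_rejected(self):
        with pytest.raises(UnknownOptionError):
            resolve(build_telegram(), TELEGRAM_ARGS + ["-bogus", "1"])

    def test_deterministic(self):
        a = resolve(build_telegram(), TELEGRAM_ARGS)
        b = resolve(build_telegram(), TELEGRAM_ARGS)
        assert export_graph(a, "process") == export_graph(b, "process")
        assert [c.fifo_basename for c in a.channels] == [
            c.fifo_basename for c in b.channels
        ]


class TestConnectErrors:
    def test_input_to_input_direction_mismatch(self):
        program = ProgramSpec("m")
        program.register_process(
            ProcessSpec(
                name="a",
                body=BodySpec.command("true"),
                ports=(PortSpec("-inx", payload="stream"),),
                connect=(FifoOpt("-inx"),),
            )
        )
        program.register_process(
            ProcessSpec(
                name="b",
                body=BodySpec.command("true"),
                ports=(PortSpec("-iny", payload="stream"),),
                connect=(FromProcessOut("-iny", "a", "-inx"),),
            )
        )
        with pytest.raises(DirectionMismatchError):
            resolve(program)

    def test_unknown_producer(self):
        program = ProgramSpec("m")
        program.register_process(
            ProcessSpec(
                name="b",
                body=BodySpec.command("true"),
                ports=(PortSpec("-inf", payload="stream"),),
                connect=(FromProcessOut("-inf", "ghost", "-outf"),),
            )
        )
        with pytest.raises(UnknownProcessError):
            resolve(program)

    def test_single_producer_rule(self):
        program = ProgramSpec("m")
        program.register_process(_step("a"))
        program.register_process(_step("b"))
        program.register_process(
            ProcessSpec(
                name="c",
                body=BodySpec.command("true"),
                ports=(PortSpec("-inf", payload="path"),),
                connect=(
                    FromProcessOut("-inf", "a", "-outf"),
                    FromProcessOut("-inf", "b", "-outf"),
                ),
            )
        )
        with pytest.raises(DuplicateNameError):
            resolve(program)

    def test_fifo_basename_collision(self):
        program = ProgramSpec("m")
        program.register_process(
            ProcessSpec(
                name="p",
                body=BodySpec.command("true"),
                ports=(
                    PortSpec("-outx", payload="stream"),
                    PortSpec("--out-x", payload="stream", required=False),
                ),
                connect=(FifoOpt("-outx"), FifoOpt("--out-x")),
            )
        )
        with pytest.raises(DuplicateNameError):
            resolve(program)

    def test_job_step_cannot_use_streams(self):
        program = ProgramSpec("m")
        program.register_process(
            ProcessSpec(
                name="s",
                body=BodySpec.command("true"),
                ports=(PortSpec("-in", payload="stream"),),
                exec_class="job_step",
                connect=(FifoOpt("-in"),),
            )
        )
        with pytest.raises(DefinitionError):
            resolve(program)


class TestExternalFifos:
    def test_paper_fifo_names(self):
        net = resolve(build_master_worker_triggered(), ["-inn", "10"])
        names = {c.fifo_basename for c in net.stream_channels()}
        assert {"master_trigger", "worker_threshold"} <= names

    def test_counter_and_echo_names(self):
        assert {
            c.fifo_basename
            for c in resolve(build_counter(), ["-inn", "3"]).stream_channels()
        } == {"counter_out"}
        assert {
            c.fifo_basename
            for c in resolve(build_stream_echo(), []).stream_channels()
        } == {"stream_echo_in"}


class TestCyclicity:
    def test_master_worker_cyclic(self):
        assert resolve(build_master_worker(), MW_ARGS).cyclic is True

    def test_telegram_acyclic(self):
        assert resolve(build_telegram(), TELEGRAM_ARGS).cyclic is False

    def test_random_networks_match_bruteforce_oracle(self):
        rng = random.Random(20240917)
        for _trial in range(40):
            n = rng.randint(2, 6)
            names = [f"p{i}" for i in range(n)]
            edges = []
            for u in range(n):
                for v in range(n):
                    if u != v and rng.random() < 0.25:
                        edges.append((u, v))
            program = ProgramSpec("rand")
            ports = {i: [] for i in range(n)}
            connects = {i: [] for i in range(n)}
            for e, (u, v) in enumerate(edges):
                ports[u].append(PortSpec(f"-out{e}", payload="stream"))
                ports[v].append(PortSpec(f"-in{e}", payload="stream"))
                connects[v].append(
                    FromProcessOut(f"-in{e}", names[u], f"-out{e}")
                )
            for i in range(n):
                # ensure every process is an FBP process even when isolated
                ports[i].append(
                    PortSpec(f"-outx{i}", payload="stream", required=False)
                )
                program.register_process(
                    ProcessSpec(
                        name=names[i],
                        body=BodySpec.command("true"),
                        ports=tuple(ports[i]),
                        connect=tuple(connects[i]),
                    )
                )
            net = resolve(program)
            # brute-force oracle: look for any directed cycle by enumeration
            edge_set = {(names[u], names[v]) for u, v in edges}
            has_cycle = False
            for k in range(1, n + 1):
                for perm in itertools.permutations(names, k):
                    if all(
                        (perm[i], perm[(i + 1) % k]) in edge_set
                        for i in range(k)
                    ):
                        has_cycle = True
                        break
                if has_cycle:
                    break
            assert net.cyclic == has_cycle

    def test_locality_of_reconfiguration(self):
        def build(with_alt_tail):
            program = ProgramSpec("m")
            program.register_process(_step("a"))
            program.register_process(_step("b"))
            tail_connect = (
                FromProcessOut("-inf", "b" if with_alt_tail else "a", "-outf"),
            )
            program.register_process(
                ProcessSpec(
                    name="tail",
                    body=BodySpec.command("true"),
                    ports=(PortSpec("-inf", payload="path"),),
                    connect=tail_connect,
                )
            )
            return resolve(program)

        base, alt = build(False), build(True)

        def untouched(net):
            return [
                (c.producer.process, c.consumer.process, c.medium)
                for c in net.channels
                if "tail" not in (c.producer.process, c.consumer.process)
            ]

        assert untouched(base) == untouched(alt)
        assert untouched(base) == []  # a and b feed only tail here


class TestDependencyGraph:
    def test_host_workflow_edge(self):
        net = resolve(build_host_workflow(2))
        g = build_dependency_graph(net)
        assert list(g.edges) == [("host1", "host2")]

    def test_single_process_no_edges(self):
        program = ProgramSpec("m")
        program.register_process(_step("only"))
        g = build_dependency_graph(resolve(program))
        assert list(g.nodes) == ["only"] and not list(g.edges)

    def test_diamond_against_enumeration_oracle(self):
        net = resolve(_diamond())
        g = build_dependency_graph(net)
        assert set(g.edges) == {("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")}
        # oracle: enumerate every permutation, keep the linear extensions
        valid = [
            p
            for p in itertools.permutations("abcd")
            if all(p.index(u) < p.index(v) for u, v in g.edges)
        ]
        assert all(p[0] == "a" and p[-1] == "d" for p in valid)
        assert sorted(map(tuple, nx.all_topological_sorts(g))) == sorted(valid)

    def test_warning_for_unconsumed_documented_option(self):
        program = build_telegram()
        program.document_option("wseq", "-ghost", "string", "never used")
        net = resolve(program, TELEGRAM_ARGS)
        assert any("-ghost" in w for w in net.warnings)


class TestExportGraph:
    def test_telegram_process_nodes(self):
        dot = export_graph(resolve(build_telegram(), TELEGRAM_ARGS), "process")
        for name in ("rseq", "decomposer", "recomposer", "wseq"):
            assert f'"{name}" [shape=box];' in dot
        assert dot.startswith("digraph process {")

    def test_empty_program(self):
        dot = export_graph(resolve(ProgramSpec("empty")), "process")
        assert dot == "digraph process {\n}\n"

    def test_master_worker_two_cycle(self):
        dot = export_graph(resolve(build_master_worker(), MW_ARGS), "process")
        assert '"master" -> "worker"' in dot
        assert '"worker" -> "master"' in dot

    def test_dependency_kind(self):
        dot = export_graph(resolve(_diamond()), "dependency")
        assert '"a" -> "b";' in dot and '"c" -> "d";' in dot

    def test_external_endpoints_drawn_distinctly(self):
        dot = export_graph(resolve(build_counter(), ["-inn", "1"]), "process")
        assert '"counter_out" [shape=ellipse];' in dot
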