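# fifoflow

A flow-based-programming (FBP) workflow engine. Programs are networks of
port-addressed processes: long-lived **FBP processes** communicate over
named pipes (FIFOs), control their own life cycle and may hold state —
which makes cyclic, interactive, trigger-driven and runtime-piped
workflows possible — while stateless **job steps** communicate over files
and are scheduled either reactively (dynamic scheduling) or by compiling
the whole dependency graph into a minimal array-job submission plan up
front (static scheduling).

## Highlights

- **Port-prefix rule**: option tokens starting with `-out`/`--out` are
  output ports, everything else is an input port.
- **Channels**: stream channels are OS named pipes created under
  `__fifos__/` *before* any process starts; file channels live under the
  producer's output directory. Records are newline-delimited bytes; EOF is
  the end-of-stream.
- **Exposed FIFOs**: external ports surface as named pipes
  (`master_trigger`, `worker_threshold`, `counter_out`, …) so a user — or
  another running program, via `fifoflow.bridge` — can interact with a
  live workflow.
- **Static scheduler**: one array job per process template regardless of
  array size, submitted in a single pass with pre-resolved `afterok`
  dependencies; after submission the engine is quiescent. Backends:
  `local` (built-in first-fit allocator over cpus/memory) and `mock`
  (recording stand-in for an external batch scheduler).
- **Dynamic scheduler**: event-driven reactive activation of job steps,
  plus a computation pool that running stateful processes can submit work
  to at runtime.
- **Life-cycle tracking**: per-task states
  (`pending/in_progress/completed/failed/stopped`) are persisted under
  `__exec__/` after every transition; `status` and `stop` work from any
  process, and re-execution resumes past completed processes whose
  resolved options are unchanged.

## CLI

```sh
# run the bundled Telegram text-reflow network (4 processes over 3 FIFOs)
fifoflow exec telegram --outdir out -- -f input.txt -l 25

# cyclic master-worker with a stateful worker
fifoflow exec master_worker --outdir mw -- -invalue 0 -inn 10 -inthreshold 5

# two-step array workflow, statically planned: exactly 2 submissions
fifoflow exec host_workflow --outdir hw --scheduler static --backend mock -- -n 10000
cat hw/__exec__/plan

fifoflow status --outdir out --porcelain
fifoflow stop   --outdir out
fifoflow graphs telegram --outdir out -- -f input.txt -l 25
```

`exec` produces an output tree with one directory per process (captured
`stdout`/`stderr`, output files), `__exec__/` (state logs, plan,
fingerprints), `__fifos__/` (exposed pipes) and `__graphs__/`
(deterministic DOT process/dependency graphs). Exit codes: 0 completed,
1 failed, 2 stopped, 3 usage error.

Programs are either catalog names (`telegram`, `telegram_steps`,
`master_worker`, `master_worker_triggered`, `master_worker_dynamic`,
`counter`, `stream_echo`, `host_process`, `host_workflow`) or YAML
program-definition files (`fifoflow.dump_program` / `load_program`).

### Runtime piping

Two independently launched programs can be joined through their exposed
FIFOs while running:

```python
import fifoflow as ff
ff.bridge("counter_outdir", "counter_out", "echo_outdir", "stream_echo_in")
```

## Library sketch

```python
import fifoflow as ff

program = ff.ProgramSpec("my_module")
program.register_process(ff.ProcessSpec(
    name="squarer",
    body=ff.BodySpec.script("...", "python"),
    ports=(ff.PortSpec("-in", payload="stream"),
           ff.PortSpec("-out", payload="stream")),
    connect=(ff.FifoOpt("-in"), ff.FifoOpt("-out")),
))
network = ff.resolve(program, [])
report = ff.execute(network, "outdir")          # dynamic scheduling
plan = ff.build_plan(network)                   # static plan (job steps only)
```

Connection rules are either an eager list of directives (`CmdlineOpt`,
`ValueOpt`, `FromProcessOut`, `FifoOpt`, `OutFile`) or a generator
yielding one directive list per array task.

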