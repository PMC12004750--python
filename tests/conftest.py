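import threading

import pytest

from fifoflow import EngineConfig, LocalCapacity, execute


@pytest.fixture
def patient_config():
    """Engine config with the deadlock watchdog effectively disabled."""
    return EngineConfig(deadlock_timeout=3600.0, capacity=LocalCapacity(8, 32768))


class AsyncRun:
    """Run execute() in a background thread; join() returns the RunReport."""

    def __init__(self, network, root, **kwargs):
        self.report = None
        self.error = None

        def _target():
            try:
                self.report = execute(network, root, **kwargs)
            except BaseException as exc:
                self.error = exc

        self.thread = threading.Thread(target=_target, daemon=True)
        self.thread.start()

    def join(self, timeout=60):
        self.thread.join(timeout)
        if self.thread.is_alive():
            raise TimeoutError("engine run did not finish in time")
        if self.error is not None:
            raise self.error
        return self.report


@pytest.fixture
def run_async():
    return AsyncRun
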