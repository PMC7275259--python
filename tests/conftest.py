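import numpy as np
import pytest

from apneaflow import evalharness, synthdata
from apneaflow.flowproc import FlowSequence
from apneaflow.windowing import ApneaEvent

#: Reduced-size benchmark configuration shared by determinism checks.
MINI_BENCHMARK = dict(
    n_room1=6, n_test=4, subjects_per_room=3, duration_range=(15.0, 18.0),
    cnn_epochs=2, cnn_patience=2, b3_epochs=2, b3_patience=2,
)


@pytest.fixture(scope="session")
def mini_benchmark_tables(tmp_path_factory):
    """Two identical reduced benchmark runs (tables and raw result files)."""
    out = tmp_path_factory.mktemp("bench")
    tables, payloads = [], []
    for run in range(2):
        path = out / f"results_{run}.tsv"
        config = evalharness.BenchmarkConfig(seed=9, **MINI_BENCHMARK)
        tables.append(evalharness.run_benchmark(config, out_path=path))
        payloads.append(path.read_bytes())
    return tables, payloads


@pytest.fixture
def scene():
    return synthdata.default_scene((48, 64))


@pytest.fixture
def zero_flow():
    """40 s of all-zero flow at 2 Hz on a small frame."""
    return FlowSequence(fields=np.zeros((80, 8, 8, 2), dtype=np.float32), fps=2.0)


@pytest.fixture
def event_10s():
    return ApneaEvent(recording_id="r0", start=10.0, end=20.0, label="CA")


def region_mean_y(fields: np.ndarray, box) -> np.ndarray:
    """Mean y-flow inside a box, per frame (shared test helper)."""
    rows, cols = synthdata.region_slices(box)
    return fields[:, rows, cols, 1].mean(axis=(1, 2))
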