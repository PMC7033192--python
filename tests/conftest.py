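import numpy as np
import pytest

import graphdmd as g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_snapshots(rng):
    """Constant symmetric adjacency sequence (fixed point of the dynamics)."""
    A0 = rng.uniform(0.1, 1.0, size=(5, 5))
    A0 = 0.5 * (A0 + A0.T)
    return g.SnapshotTensor(np.repeat(A0[:, :, None], 12, axis=2), dt=0.04)


def random_symmetric_tensor(rng, m, T):
    X = rng.normal(size=(m, m, T))
    return g.SnapshotTensor(0.5 * (X + X.transpose(1, 0, 2)), dt=0.04)


@pytest.fixture(scope="session")
def labelled_dataset():
    """40 synthetic segments whose labels differ only by the D1-D2 oscillation."""
    segments, manifest = g.generate_dataset(20, base_seed=20260922)
    return segments, manifest


@pytest.fixture(scope="session")
def end_to_end_result(labelled_dataset):
    """Full pipeline output on the labelled dataset (shared; ~3 s)."""
    segments, _ = labelled_dataset
    config = g.PipelineConfig(seed=20260922)
    return g.run_end_to_end(segments, config)
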