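import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from voxstitch import synthetic_data


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """2x2 noiseless zero-jitter dataset: adjacent overlap strips are
    voxel-identical by construction."""
    out = tmp_path_factory.mktemp("clean_ds")
    project, truth = synthetic_data.make_dataset(
        str(out),
        m=2,
        n=2,
        tile_shape=(16, 48, 48),
        overlap=(12, 12),
        jitter_bound=0,
        noise_sigma=0.0,
        seed=11,
        substack_count=1,
    )
    return project, truth


@pytest.fixture(scope="session")
def jittered_dataset(tmp_path_factory):
    """3x3 noiseless dataset with known jitter (J=3), S=2 sub-stacks."""
    out = tmp_path_factory.mktemp("jit_ds")
    project, truth = synthetic_data.make_dataset(
        str(out),
        m=3,
        n=3,
        tile_shape=(24, 48, 48),
        overlap=(14, 14),
        jitter_bound=3,
        noise_sigma=0.0,
        seed=23,
        substack_count=2,
    )
    return project, truth
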