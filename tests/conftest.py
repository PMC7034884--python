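import numpy as np
import pytest

from chronomid.imaging_io import DatasetIndex, SliceRecord
from chronomid.synthdata import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """A small but structurally complete study: 2 mice/group, 4 weeks minus
    the missing week, fixed 4 slices per mouse-week."""
    return SynthConfig(
        n_mice_per_group=2,
        weeks=tuple(range(4)),
        missing_weeks=frozenset({2}),
        slices_range=(4, 4),
        height_range=(40, 48),
        width_range=(40, 48),
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


def make_index(records):
    return DatasetIndex(records)


def record(pixels, mouse="m0", week=0, k=0, label="wild"):
    return SliceRecord(
        mouse_id=mouse, week=week, slice_index=k, label=label, pixels=np.asarray(pixels)
    )


@pytest.fixture
def grid_record():
    return record([[5, 3], [2, 8]])
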