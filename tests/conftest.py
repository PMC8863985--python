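import numpy as np
import pytest

from babytract.phantom import PhantomConfig, generate_phantom
from babytract.pipeline import profile_phantom_sessions
from babytract.segmentation import segment_all


@pytest.fixture(scope="session")
def tiny_phantom():
    """A small but complete cohort: 24 bundles, 29 sessions, R1 + MD."""
    cfg = PhantomConfig(seed=23, streamlines_per_bundle=8, n_distractors=40)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def tiny_bundles(tiny_phantom):
    return segment_all(tiny_phantom.streamlines, tiny_phantom.atlas)


@pytest.fixture(scope="session")
def tiny_profile_table(tiny_phantom, tiny_bundles):
    import pandas as pd

    r1 = profile_phantom_sessions(tiny_phantom, tiny_bundles, "r1")
    md = profile_phantom_sessions(tiny_phantom, tiny_bundles, "md")
    return pd.concat([r1, md], ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
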