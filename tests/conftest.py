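import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `helpers`

from fasworm import pipeline as pl  # noqa: E402


@pytest.fixture(scope="session")
def oscillator_baseline():
    """Healthy baseline of the oscillator fixture, computed once per session.

    Returns (config, connectome, params, I_ext, rest_state, plane,
    healthy_shape, healthy_frequency).
    """
    cfg = pl.EnsembleConfig(K=1, seed=1)
    c, params, I_ext, rest, plane, shape, freq = pl.healthy_baseline(cfg)
    return cfg, c, params, I_ext, rest, plane, shape, freq
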