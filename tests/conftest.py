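import numpy as np
import pandas as pd
import pytest

from nc886.epigenotyping import BetaMatrix, DEFAULT_PROBES


@pytest.fixture
def make_matrix():
    """Build a BetaMatrix from per-sample probe beta lists over the default probes."""

    def _make(sample_betas: dict[str, list[float]], probe_ids=None) -> BetaMatrix:
        probes = list(probe_ids) if probe_ids is not None else list(DEFAULT_PROBES.probe_ids)
        n = len(probes)
        cols = {}
        for sid, betas in sample_betas.items():
            col = list(betas) + [np.nan] * (n - len(betas))
            cols[sid] = col[:n]
        return BetaMatrix(pd.DataFrame(cols, index=probes))

    return _make


@pytest.fixture
def blood_config():
    from nc886.synthetic_data import make_config

    return make_config("blood")
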