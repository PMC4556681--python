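import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def toy_matrix():
    """4 genes x 6 samples, fixed values spanning a realistic Ct range."""
    rng = np.random.default_rng(42)
    genes = ["gA", "gB", "gC", "gD"]
    samples = [f"s{i}" for i in range(1, 7)]
    return pd.DataFrame(np.round(20 + 8 * rng.random((4, 6)), 3),
                        index=genes, columns=samples)


@pytest.fixture
def toy_groups():
    return {f"s{i}": ("control" if i <= 3 else "treated") for i in range(1, 7)}


@pytest.fixture
def toy_design(toy_groups):
    from helpers import build_design
    samples = list(toy_groups)
    return build_design(samples, [toy_groups[s] for s in samples], "control")
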