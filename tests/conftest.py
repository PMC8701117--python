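import numpy as np
import pandas as pd
import pytest

from twindiff.containers import BetaMatrix, SimConfig


@pytest.fixture
def small_beta() -> BetaMatrix:
    """Hand-sized beta matrix: 4 probes, 3 discordant pairs."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.uniform(0.2, 0.8, size=(4, 6)),
        index=[f"cg{i}" for i in range(4)],
        columns=["a1", "u1", "a2", "u2", "a3", "u3"],
    )
    pairs = {"p1": ("a1", "u1"), "p2": ("a2", "u2"), "p3": ("a3", "u3")}
    return BetaMatrix(values, pairs)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic twin dataset shared across tests."""
    from twindiff.synthetic import generate_twin_beta

    cfg = SimConfig(seed=11)
    beta, truth = generate_twin_beta(cfg)
    return cfg, beta, truth
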