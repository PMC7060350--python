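import numpy as np
import pandas as pd
import pytest

from varlocus import simulate as sim


@pytest.fixture(scope="session")
def default_cfg():
    return sim.SimConfig(seed=1)


@pytest.fixture(scope="session")
def panel_and_truth(default_cfg):
    return sim.simulate_genotype_panel(default_cfg)


@pytest.fixture(scope="session")
def locus(default_cfg):
    """One fully simulated locus shared across the end-to-end style tests."""
    return sim.simulate_locus(default_cfg)


def make_panel(columns, positions=None):
    """Build a PhasedPanel directly from 0/1 haplotype columns (for oracles)."""
    from varlocus.ldmap import PhasedPanel

    H = np.column_stack([np.asarray(c, dtype=np.uint8) for c in columns])
    n_hap, m = H.shape
    assert n_hap % 2 == 0
    pos = positions or list(range(100, 100 + 10 * m, 10))
    snps = pd.DataFrame({
        "id": [f"s{i}" for i in range(m)],
        "pos": pos,
        "ref": ["A"] * m,
        "alt": ["C"] * m,
    })
    return PhasedPanel(
        snps=snps, haplotypes=H,
        samples=[f"x{i}" for i in range(n_hap // 2)],
        populations=np.array(["ALL"] * (n_hap // 2)),
    )
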