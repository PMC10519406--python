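import numpy as np
import pandas as pd
import pytest

import epistate as ep


@pytest.fixture(scope="session")
def small_panel():
    """Null panel (all state effects zero), small but structurally complete."""
    cfg = ep.SimConfig(n_genes=60, seed=101)
    return ep.simulate_founder_panel(cfg)


@pytest.fixture(scope="session")
def effect_panel():
    """Panel with a strong positive effect of state 1 and negative of state 2."""
    cfg = ep.SimConfig(n_genes=250, seed=7,
                       state_betas=np.r_[1.0, -1.0, np.zeros(12)])
    return ep.simulate_founder_panel(cfg)


@pytest.fixture(scope="session")
def effect_props(effect_panel):
    return {s: ep.state_proportions(t, effect_panel.genes, 14)
            for s, t in effect_panel.tracks.items()}


@pytest.fixture(scope="session")
def do_panel():
    """Panel + DO population with a causal state-5 effect at a known position."""
    cfg = ep.SimConfig(n_genes=12, n_do=200, seed=42,
                       state_betas=np.r_[np.zeros(4), 2.0, np.zeros(9)])
    panel = ep.simulate_founder_panel(cfg)
    do = ep.simulate_do_population(panel.config, panel)
    return panel, do


@pytest.fixture()
def toy_genes():
    return pd.DataFrame({
        "gene_id": ["gA", "gB"],
        "chrom": ["chr1", "chr1"],
        "start": [1000, 10000],
        "end": [3000, 12000],
        "strand": ["+", "-"],
    })
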