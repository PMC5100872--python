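import numpy as np
import pandas as pd
import pytest

from gptrainsel import (
    MarkerPanel,
    SyntheticPanelConfig,
    additive_relationship,
    ibs_matrix,
    simulate_panel,
)


@pytest.fixture
def tiny_panel():
    """5 genotypes x 8 markers, deterministic, fully observed, polymorphic."""
    rng = np.random.default_rng(123)
    dosage = rng.choice([0, 2], size=(5, 8), p=[0.5, 0.5]).astype(np.int8)
    dosage[0, 0] = 0
    dosage[1, 0] = 2  # guarantee polymorphism at marker 0
    for j in range(8):  # force every marker polymorphic
        if len(set(dosage[:, j])) == 1:
            dosage[0, j] = 2 - dosage[0, j]
    return MarkerPanel(
        [f"g{i}" for i in range(5)],
        [f"m{j}" for j in range(8)],
        np.array(["1", "1", "1", "1", "2", "2", "2", "2"], dtype=object),
        np.array([0.0, 10.0, 20.0, 30.0, 0.0, 10.0, 20.0, 30.0]),
        dosage,
    )


@pytest.fixture(scope="session")
def struct_panel():
    """Small structured panel with families (n=100) shared across tests."""
    cfg = SyntheticPanelConfig(subpop_sizes=(40, 25, 20, 15), n_markers=400,
                               n_chromosomes=4, seed=7)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def struct_kinships(struct_panel):
    panel, _ = struct_panel
    return ibs_matrix(panel), additive_relationship(panel)


@pytest.fixture(scope="session")
def bn_panel():
    """Plain Balding-Nichols two-population panel (no family layer)."""
    cfg = SyntheticPanelConfig(subpop_sizes=(60, 60), fst=0.2, n_markers=800,
                               n_chromosomes=4, singleton_frac=1.0,
                               singleton_fst=0.0, diversity_spread=1.0, seed=3)
    return simulate_panel(cfg)


def make_csv_panel(tmp_path, panel):
    """Write a panel to CSV + map files and return their paths."""
    from gptrainsel import write_panel

    gpath = tmp_path / "panel.csv"
    mpath = tmp_path / "map.csv"
    write_panel(panel, gpath, mpath)
    return gpath, mpath
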