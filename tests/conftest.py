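import numpy as np
import pandas as pd
import pytest

import circfish as cf


@pytest.fixture(scope="session")
def noise_free_scene():
    """Two-cell, fixed-count, noise-free scene shared by detection/quant tests."""
    cfg = cf.SimulationConfig(
        field_shape=(16, 256, 256),
        n_cells=2,
        rng_seed=7,
        noise=False,
        count_model="fixed",
    )
    nuclear, cells = cf.generate_cells(cfg)
    gt = cf.sample_molecules(cfg, nuclear, cells)
    stack = cf.render(gt, cfg)
    return cfg, gt, stack


@pytest.fixture(scope="session")
def single_molecule_stack():
    """One linear molecule at the stack centre, noise and jitter off."""
    cfg = cf.SimulationConfig(
        field_shape=(16, 64, 64),
        n_cells=1,
        rng_seed=0,
        noise=False,
        registration_sd_nm=0.0,
    )
    maps = np.ones((64, 64), dtype=np.int32)
    mols = _molecule_table([(1500.0, 4100.0, 4200.0)], "linear")
    gt = cf.GroundTruth(mols, maps, maps, cfg)
    return cfg, gt, cf.render(gt, cfg)


def _molecule_table(positions_nm, rna_class, cell_id=1):
    rows = []
    for i, (z, y, x) in enumerate(positions_nm):
        rows.append(
            {
                "molecule_id": i,
                "cell_id": cell_id,
                "rna_class": rna_class,
                "z_nm": z,
                "y_nm": y,
                "x_nm": x,
                "compartment": "cytoplasmic",
                "decay_u": 0.5,
                "kd_u": 0.5,
            }
        )
    cols = [
        "molecule_id", "cell_id", "rna_class", "z_nm", "y_nm", "x_nm",
        "compartment", "decay_u", "kd_u",
    ]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def molecule_table():
    return _molecule_table
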