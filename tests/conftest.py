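import numpy as np
import pytest

import spatialsel as ss


@pytest.fixture(scope="session")
def tiny_data():
    """Tiny benchmark at default noise (shared across tests; read-only)."""
    raw, norm, atlas, truth = ss.make_dataset("tiny", seed=11)
    return raw, norm, atlas, truth


@pytest.fixture(scope="session")
def tiny_mcc(tiny_data):
    """Binarization + MCC map for the tiny dataset's atlas genes."""
    _, norm, atlas, _ = tiny_data
    params = ss.fit_binarization(norm.subset_genes(atlas.gene_names), atlas)
    mcc_map = ss.compute_mcc_map(
        ss.binarize_cells(norm, params), atlas, atlas.gene_names,
        cell_names=list(norm.cell_names),
    )
    return params, mcc_map


@pytest.fixture(scope="session")
def noiseless_data():
    """Zero-noise cells: binarization should recover bins exactly."""
    coords = ss.simulate_embryo_bins(40, seed=1)
    atlas = ss.simulate_atlas_patterns(coords, 12, seed=2)
    raw, norm, truth = ss.simulate_cells(
        atlas, 200, n_noise_genes=0, n_decoys=0,
        noise_sd=0.0, dropout_p=0.0, seed=3,
    )
    return norm, atlas, truth


@pytest.fixture(scope="session")
def small_expr():
    rng = np.random.default_rng(0)
    return ss.ExpressionMatrix(
        gene_names=[f"g{i}" for i in range(5)],
        cell_names=[f"c{j}" for j in range(4)],
        values=rng.uniform(0, 10, size=(5, 4)),
    )
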