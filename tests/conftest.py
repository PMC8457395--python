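import numpy as np
import pytest

from shiftgnn import ModelConfig, RBFParams, build_graph, make_labelled
from shiftgnn import synthetic as syn
from shiftgnn.gnn import init_model


@pytest.fixture(scope="session")
def tiny_config():
    """Small float64 model for fast exact tests."""
    return ModelConfig(
        feature_dim=16,
        n_basis=16,
        n_update_blocks=2,
        readout_layer_widths=(16, 8, 1),
        nucleus="C13",
        seed=7,
        dtype="float64",
    )


@pytest.fixture(scope="session")
def rbf16():
    return RBFParams(n_basis=16)


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return init_model(tiny_config)


def oracle_dataset(n, seed, rbf, nucleus="C13", jitter=0.1):
    """Labelled graphs over perturbed fixture geometries."""
    out = []
    for mol, conf in syn.perturbed_conformer_set(n, seed=seed, jitter=jitter):
        graph = build_graph(conf, mol, rbf, nucleus)
        out.append(make_labelled(graph, syn.oracle_shifts(conf, mol, nucleus=nucleus)))
    return out


@pytest.fixture(scope="session")
def tiny_oracle_data(rbf16):
    return oracle_dataset(40, seed=11, rbf=rbf16)


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))
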