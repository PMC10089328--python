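import numpy as np
import pytest

from geociaf import (
    ChainConfig,
    ModelSpec,
    SmoothTerm,
    SpatialTerm,
    default_truth,
    make_lattice_graph,
    simulate_dataset,
)
from geociaf.model import fit as fit_model

RECOVERY_BETA = {
    "intercept": -0.3,
    "gender=male": float(np.log(1.315)),
    "diarrhoea=yes": float(np.log(1.256)),
    "media_exposure=yes": float(np.log(0.858)),
}

RECOVERY_MIX = {
    "gender": {"female": 0.49, "male": 0.51},
    "diarrhoea": {"no": 0.87, "yes": 0.13},
    "media_exposure": {"no": 0.40, "yes": 0.60},
}

RECOVERY_SPEC = ModelSpec(
    fixed_terms=(("gender", "female"), ("diarrhoea", "no"), ("media_exposure", "no")),
    smooth_terms=(SmoothTerm("child_age"),),
    spatial_term=SpatialTerm("region"),
)


def make_recovery_dataset(n, seed, graph, var_str=0.323, var_unstr=0.009, nonlinear=True):
    truth = default_truth(
        graph,
        seed=seed,
        beta=RECOVERY_BETA,
        var_str=var_str,
        var_unstr=var_unstr,
        nonlinear=nonlinear,
    )
    return simulate_dataset(n, graph, truth=truth, seed=seed + 1000, mix=RECOVERY_MIX)


@pytest.fixture(scope="session")
def lattice12():
    return make_lattice_graph(4, 3)


@pytest.fixture(scope="session")
def recovery_dataset(lattice12):
    return make_recovery_dataset(n=2500, seed=7, graph=lattice12)


@pytest.fixture(scope="session")
def fitted_m3(recovery_dataset, lattice12):
    """One short full-model fit shared by reporting / selection tests."""
    config = ChainConfig(iterations=900, burnin=300, thin=2, seed=11)
    return fit_model(RECOVERY_SPEC, recovery_dataset.records, lattice12, config)
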