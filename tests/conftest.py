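import numpy as np
import pytest

import sccosol as sc


@pytest.fixture(scope="session")
def decitabine():
    return sc.decitabine_dataset()


@pytest.fixture(scope="session")
def reference():
    return sc.get_density_provider("reference")


@pytest.fixture(scope="session")
def pr_eos():
    return sc.get_density_provider("pr-eos")


@pytest.fixture(scope="session")
def decitabine_X(decitabine):
    """(n, 2) sklearn design [T_K, P_MPa] and y for the packaged data."""
    T, P, y = decitabine.arrays()
    return np.column_stack([T, P]), y


# ground-truth parameter sets used to synthesize noiseless surfaces;
# magnitudes chosen so predictions stay in a physical mole-fraction range
# over the packaged T x P grid
TRUE_PARAMS = {
    "chrastil": (-20.0, -6800.0, 6.0),
    "bartle": (24.0, -9200.0, 0.011),
    "mst": (-12000.0, 25.0, 3.6),
    "kj": (7.8, -7327.4, 0.348),
    "garlapati_madras": (-55.0, -5200.0, 5.0),
}


@pytest.fixture(scope="session")
def noiseless():
    """model_id -> (config, dataset) noiseless synthetic surfaces."""
    out = {}
    for mid, p in TRUE_PARAMS.items():
        cfg = sc.SyntheticConfig(
            model_id=mid, true_params=sc.ModelParameters(*p),
            noise_sigma=0.0, seed=1)
        out[mid] = (cfg, sc.generate(cfg))
    return out
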