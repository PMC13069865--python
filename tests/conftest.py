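import numpy as np
import pytest

from cobindlm.encoding import encode_matrix
from cobindlm.synthetic import (
    SyntheticConfig,
    generate_catalog,
    generate_region_labels,
    generate_signal_matrix,
)


@pytest.fixture(scope="session")
def tiny_config():
    # small but structured: 12 regulators x 2 cistromes, 3 modules, 400 regions
    return SyntheticConfig(n_regulators=12, cistromes_per_regulator=2,
                           n_modules=3, n_regions=400, n_drivers=3, seed=7)


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    catalog, truth = generate_catalog(tiny_config)
    matrix, peaks = generate_signal_matrix(catalog, truth, tiny_config)
    labels = generate_region_labels(truth, peaks, "binary", tiny_config, catalog)
    tokens = encode_matrix(matrix)
    return {"config": tiny_config, "catalog": catalog, "truth": truth,
            "matrix": matrix, "peaks": peaks, "labels": labels, "tokens": tokens}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
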