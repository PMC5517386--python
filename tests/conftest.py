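import numpy as np
import pytest
from hypothesis import settings

import cardiophantom as cp

settings.register_profile("deterministic", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("deterministic")

SWEEP_SEED = 11


@pytest.fixture(scope="session")
def phantom65():
    return cp.PhantomConfig(ef_nominal=65, seed=1)


@pytest.fixture(scope="session")
def ei_sweep(phantom65):
    """Full EI sweep at the default study conditions (both protocols, both
    delineation surrogates, 8 gates, 64x64x32 grid).  Shared across the
    convergence-behaviour tests; ~1 minute."""
    return cp.run_study(phantom65, protocols=("LEHR", "IQSPECT"),
                        methods=("radial_gaussian", "count_threshold"),
                        seed=SWEEP_SEED, matrix=64, nz=32)
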