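import numpy as np
import pytest

import rsndyn as r


@pytest.fixture(scope="session")
def var3_session():
    """A small 3-network diagonal-AR(1) session used by several modules."""
    return r.gen_var_session(np.eye(3) * 0.3, 208, seed=11, network_labels=("DMN", "DAN", "SN"))


@pytest.fixture(scope="session")
def labels14():
    return r.DEFAULT_NETWORKS
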