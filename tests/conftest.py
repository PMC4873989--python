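import numpy as np
import pandas as pd
import pytest

from pathprofiler import ActivityMatrix, PanelSimSpec, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """3 planted classes x 5 members + 4 inactives on the 39-readout panel."""
    spec = PanelSimSpec(n_classes=3, n_per_class=5, n_inactive=4,
                        signature_sparsity=0.25, signature_scale=50.0,
                        noise_sd=10.0, seed=42)
    matrix, records, annotations, truth = generate_panel(spec)
    return spec, matrix, records, annotations, truth


@pytest.fixture
def tiny_matrix():
    """Hand-written 3-compound x 2-assay raw matrix."""
    values = pd.DataFrame(
        [[10.0, 0.0], [50.0, 5.0], [90.0, -5.0]],
        index=["C001", "C002", "C003"], columns=["CRE_inh", "CRE_act"],
    )
    return ActivityMatrix(values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
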