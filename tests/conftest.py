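import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import exportome as ex
from exportome.config import RunConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Default generative model, fixed seed."""
    return ex.SimulationParams(seed=11)


@pytest.fixture(scope="session")
def truth(params):
    return ex.generate_ground_truth(300, params)


@pytest.fixture(scope="session")
def spike():
    return ex.make_spike_standard(6, 8, 0.5, 10.0)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


def make_intensity_rows(
    protein_ids,
    intensities,
    sample_id="nuc_r1",
    role="nuclear",
    replicate=1,
    min_pep=0.001,
    unique_peptides=5,
    only_by_site=False,
):
    """Hand-build a long-form intensity table for small unit fixtures."""
    n = len(protein_ids)

    def broadcast(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n

    return pd.DataFrame(
        {
            "protein_id": list(protein_ids),
            "sample_id": broadcast(sample_id),
            "role": broadcast(role),
            "replicate": broadcast(replicate),
            "intensity": [np.nan if v is None else float(v) for v in intensities],
            "min_pep": broadcast(min_pep),
            "unique_peptides": broadcast(unique_peptides),
            "only_by_site": broadcast(only_by_site),
        }
    )
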