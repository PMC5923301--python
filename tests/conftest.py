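import numpy as np
import pandas as pd
import pytest

import venomcomp as vc
from venomcomp import io as vio


@pytest.fixture(scope="session")
def sample_metadata():
    return vio.load_sample_metadata()


@pytest.fixture(scope="session")
def venom_types(sample_metadata):
    return {m.sample_id: m.venom_type for m in sample_metadata}


@pytest.fixture(scope="session")
def toxin_expression():
    """(ExpressionMatrix, TranscriptCatalog) from the packaged TPM table."""
    return vio.load_toxin_expression()


@pytest.fixture(scope="session")
def toxin_presence():
    return vio.load_toxin_presence()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def tiny_expression():
    """A 3-sample x 4-transcript TPM matrix with zeros, rows summing to 1e6."""
    values = pd.DataFrame(
        {
            "TOX-1": [500_000.0, 0.0, 250_000.0],
            "TOX-2": [0.0, 400_000.0, 250_000.0],
            "NT-1": [300_000.0, 300_000.0, 250_000.0],
            "NT-2": [200_000.0, 300_000.0, 250_000.0],
        },
        index=["s1", "s2", "s3"],
    )
    return vc.ExpressionMatrix(values, scale="tpm")
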