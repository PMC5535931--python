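import numpy as np
import pandas as pd
import pytest

from apmspipe.design_io import CountMatrix
from apmspipe.examples import ezh2_example_manifest
from apmspipe.simulate import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def manifest13():
    """The 13-sample worked-example design (7 bait, 5 IgG, 1 pan-methyl)."""
    return ezh2_example_manifest()


@pytest.fixture(scope="session")
def small_matrix(manifest13):
    """Hand-written 4-protein matrix over the 13-sample design."""
    rng = np.random.default_rng(42)
    samples = manifest13.sample_ids
    df = pd.DataFrame(
        rng.poisson(2.0, size=(4, len(samples))),
        index=[f"Q{i}" for i in range(4)],
        columns=samples,
    ).astype(np.int64)
    df.index.name = "protein_id"
    return CountMatrix(df=df)


@pytest.fixture(scope="session")
def study():
    """One medium synthetic study reused across tests (read-only)."""
    return generate_study(SimulationConfig(seed=11, n_proteins=200, n_true_interactors=10, n_condition_specific=4, n_methyl_sites=12))
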