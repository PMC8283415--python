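import numpy as np
import pandas as pd
import pytest

from assemblage.core_io import OtuTable, SampleMetadata
from assemblage.synthetic_data import (
    simulate_gradient,
    simulate_neutral,
    simulate_phylogeny,
    tiny_config,
)


@pytest.fixture(scope="session")
def tiny_tree_traits():
    cfg = tiny_config(seed=7)
    return simulate_phylogeny(cfg.n_otus, seed=7, trait_var=cfg.trait_model_var)


@pytest.fixture(scope="session")
def tiny_neutral():
    cfg = tiny_config(seed=7, m=1.0)
    return simulate_neutral(cfg)


@pytest.fixture(scope="session")
def tiny_gradient(tiny_tree_traits):
    cfg = tiny_config(seed=7)
    _, traits = tiny_tree_traits
    return simulate_gradient(cfg, traits)


@pytest.fixture()
def small_table():
    """3 samples x 4 OTUs with hand-picked counts."""
    return OtuTable(
        counts=np.array([[10, 5, 0, 1], [3, 3, 3, 3], [0, 0, 8, 2]]),
        sample_ids=["s1", "s2", "s3"],
        otu_ids=["o1", "o2", "o3", "o4"],
    )


@pytest.fixture()
def two_treatment_meta():
    return SampleMetadata(
        frame=pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "treatment": ["Control", "Control", "PYR", "PYR"],
                "dose": [0.0, 0.0, 100.0, 100.0],
                "replicate": [1, 2, 1, 2],
            }
        )
    )
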