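import numpy as np
import pandas as pd
import pytest

from cismediator import TrioScenario
from cismediator.studies import simulate_trio_dataset

from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mediated_dataset():
    """One large mediated-scenario replicate shared across tests."""
    scenario = TrioScenario(n_samples=2000, n_background_genes=0)
    return simulate_trio_dataset(scenario, seed=11)


@pytest.fixture
def small_annotation():
    genes = pd.DataFrame(
        {
            "chrom": ["17", "17", "2"],
            "start": [36_151_926, 46_200_000, 5_000_000],
            "end": [36_171_925, 46_220_000, 5_020_000],
        },
        index=pd.Index(["GC", "GT_FAR", "GT_OTHER"], name="gene_id"),
    )
    variant = pd.Series({"chrom": "17", "pos": 36_101_926, "ref": "G", "alt": "A"})
    return variant, genes
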