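import warnings

import pytest

from wetlandco2 import pipeline as pl
from wetlandco2 import synthetic as syn

#: Seed for the shared end-to-end run; every seeded test derives from it.
RUN_SEED = 1


@pytest.fixture(scope="session")
def run_result():
    """One full pipeline run on the seeded synthetic year, shared."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pl.run_pipeline(pl.RunConfig(seed=RUN_SEED))


@pytest.fixture(scope="session")
def syn_config():
    return syn.SyntheticConfig(seed=RUN_SEED)
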