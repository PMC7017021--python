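import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from cubdfe.spectra import DFEModel
from cubdfe.synthetic_data import SyntheticConfig, simulate_site_table


@pytest.fixture(scope="session")
def neutral_dataset():
    """Small all-neutral dataset with context/gradient structure."""
    cfg = SyntheticConfig(
        n_genes=30,
        theta=0.035,
        ne=500,
        ns=40,
        gradient_amplitude=0.2,
        seed=11,
    )
    return simulate_site_table(cfg)


@pytest.fixture(scope="session")
def selected_dataset():
    """Dataset with strong + lethal selection on preferred 4D sites."""
    cfg = SyntheticConfig(
        n_genes=40,
        theta=0.035,
        ne=500,
        ns=40,
        dfe_preferred=DFEModel(((-30.0, 0.15), ("lethal", 0.1))),
        seed=12,
    )
    return simulate_site_table(cfg)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, neutral_dataset):
    out = tmp_path_factory.mktemp("fixtures")
    neutral_dataset.write(out)
    return out
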