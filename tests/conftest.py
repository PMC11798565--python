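import numpy as np
import pandas as pd
import pytest

import prevadjust as pa


@pytest.fixture(scope="session")
def default_comp():
    return pa.default_composition()


@pytest.fixture(scope="session")
def uniform_comp():
    comp = pa.default_composition().copy()
    comp["proportion"] = 1.0 / len(comp)
    return comp


@pytest.fixture(scope="session")
def small_panel():
    """15k-row panel with features, shared across tests."""
    panel = pa.simulate_panel(pa.PopulationMix(), panel_n=15000, seed=42)
    return pa.generate_features(panel, pa.default_schema(), seed=43)


@pytest.fixture(scope="session")
def dev_set():
    """Synthetic development set with the published 223/1776 case balance."""
    classes = np.array(["sz"] * 223 + ["healthy"] * 1776, dtype=object)
    df = pd.DataFrame({"id": np.arange(len(classes)), "latent_class": classes})
    return pa.generate_features(df, pa.default_schema(), seed=11)
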