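import numpy as np
import pandas as pd
import pytest

from cenckit import ExpressionCompendium, SimulationConfig, simulate_compendium


@pytest.fixture
def small_config() -> SimulationConfig:
    """A scaled-down planted compendium: fast, but same structure."""
    return SimulationConfig(
        universe_size=1000, n_up=60, n_down=50,
        sig_epc_size=40, sig_enc_size=25,
        planted_up_in_epc=12, planted_down_in_enc=8,
        planted_up_in_enc=1, planted_down_in_epc=1,
        seed=42,
    )


@pytest.fixture
def small_compendium(small_config):
    return simulate_compendium(small_config)


@pytest.fixture
def tiny_compendium() -> ExpressionCompendium:
    """Hand-built 4-gene, 2x3-sample compendium with known group means."""
    tpm = pd.DataFrame(
        {
            "a1": [30.0, 10.0, 5.0, 100.0],
            "a2": [28.0, 12.0, 5.0, 100.0],
            "a3": [32.0, 8.0, 5.0, 100.0],
            "b1": [10.0, 30.0, 5.0, 100.0],
            "b2": [12.0, 28.0, 5.0, 100.0],
            "b3": [8.0, 32.0, 5.0, 100.0],
        },
        index=["up_gene", "down_gene", "flat_low", "flat_high"],
    )
    sheet = pd.DataFrame({
        "sample_id": list(tpm.columns),
        "group": ["a"] * 3 + ["b"] * 3,
        "clone": ["c1", "c2", "c3"] * 2,
    })
    return ExpressionCompendium(tpm=tpm, sample_sheet=sheet)
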