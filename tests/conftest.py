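import numpy as np
import pandas as pd
import pytest

from rhizotrans import SignalMatrix, SyntheticConfig, generate_dataset, validate_annotation


@pytest.fixture
def tiny_annotation() -> pd.DataFrame:
    return validate_annotation(pd.DataFrame({
        "probe_id": ["p1", "p2", "p2.r2", "s1", "s2", "c1"],
        "gene_id_v1": ["g1", "g2", "g2", None, None, None],
        "is_control": [False, False, False, True, True, True],
        "is_spike": [False, False, False, True, True, False],
        "spike_name": [None, None, None, "E1A_r60_a20", "spikeB", None],
        "spike_log_conc": [None, None, None, 3.83, 1.83, None],
    }))


@pytest.fixture
def tiny_matrix() -> SignalMatrix:
    values = pd.DataFrame(
        {"a1": [100.0, 10.0, 14.0, 6761.0, 67.6, 5.0],
         "a2": [200.0, 20.0, 28.0, 6761.0, 67.6, 5.0]},
        index=pd.Index(["p1", "p2", "p2.r2", "s1", "s2", "c1"], name="probe_id"),
    )
    cond = pd.Series({"a1": "Tv", "a2": "M+Tv"}, name="condition")
    return SignalMatrix(values, cond)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Down-scaled study design for fast end-to-end runs."""
    return SyntheticConfig(
        n_genes=800, n_duplicate_genes=20, n_other_controls=40,
        n_shared_up=15, n_maize_up=15, n_tomato_up=15, n_maize_vs_tomato=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)
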