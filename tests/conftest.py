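import numpy as np
import pandas as pd
import pytest

from symbiodrop.detection_model import DetectionMatrix
from symbiodrop.synthetic_data import ScenarioConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic scenario: ~30 species, one 5-species loss
    clade, trait-linked and background gene loss, detection layer."""
    return simulate_study(ScenarioConfig())


@pytest.fixture(scope="session")
def clean_study():
    """No background loss, no masking: the loss signal is exactly the
    symbiosis-specific genes in the loss clade."""
    return simulate_study(
        ScenarioConfig(
            n_species=12,
            loss_clade_size=3,
            n_conserved=5,
            n_symbiosis=4,
            n_background=10,
            background_loss_rate=0.0,
            genome_mask_rate=0.0,
            transcriptome_fraction=0.0,
            seed=11,
        )
    )


def small_masked_instances(n_instances: int = 25, seed: int = 2024):
    """Deterministic collection of fully masked detection matrices up to
    5 genes x 5 species, none with complete separation (so the MLE is
    finite and an external fitter can serve as oracle)."""
    rng = np.random.default_rng(seed)
    instances = []
    while len(instances) < n_instances:
        G = int(rng.integers(2, 6))
        S = int(rng.integers(2, 6))
        data = pd.DataFrame(
            rng.integers(0, 2, size=(G, S)).astype(float),
            index=[f"g{i}" for i in range(G)],
            columns=[f"s{j}" for j in range(S)],
        )
        det = DetectionMatrix(data, pd.DataFrame(True, index=data.index,
                                                 columns=data.columns))
        from _oracles import is_separated

        if not is_separated(det):
            instances.append(det)
    return instances


@pytest.fixture(scope="session")
def masked_instances():
    return small_masked_instances()
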