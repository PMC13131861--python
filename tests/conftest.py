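import numpy as np
import pandas as pd
import pytest

from sundown.synth import SynthConfig, gen_brain_behavior


@pytest.fixture(scope="session")
def planted_dataset():
    """Strong rank-1 brain-behavior structure, no missingness."""
    cfg = SynthConfig(
        seed=11, n_per_group=30, n_regions=30, n_behaviors=10,
        latent_strength=3.0, missing_rate=0.0,
    )
    brain, behavior, truth = gen_brain_behavior(cfg)
    return brain, behavior, truth


@pytest.fixture(scope="session")
def null_dataset():
    """Independent behavior and brain blocks (latent_strength = 0)."""
    cfg = SynthConfig(
        seed=12, n_per_group=8, n_regions=30, n_behaviors=10,
        latent_strength=0.0, missing_rate=0.0,
    )
    brain, behavior, truth = gen_brain_behavior(cfg)
    return brain, behavior, truth


def random_table(rng, n, cols, prefix, baseline=10.0):
    data = baseline + rng.standard_normal((n, len(cols)))
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    df.insert(1, "group", np.where(np.arange(n) < n // 2, "Ctrl", "AD"))
    return df
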