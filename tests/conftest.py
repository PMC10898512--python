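import numpy as np
import pandas as pd
import pytest

from vividness import (
    EmbeddingSpec,
    PsychometricModel,
    generate_meg_dataset,
    simulate_behavior,
)


@pytest.fixture(scope="session")
def behavior() -> pd.DataFrame:
    """A small staircased session with all 8 conditions populated."""
    tab = simulate_behavior(PsychometricModel(), n_blocks=4, trials_per_block=48, seed=11)
    counts = tab.groupby(["stimulus", "pas"]).size()
    assert len(counts) == 8, "fixture must populate all conditions"
    return tab


@pytest.fixture(scope="session")
def noiseless_graded(behavior) -> "object":
    """Noiseless abstract-graded recording on a short epoch."""
    spec = EmbeddingSpec("abstract_graded", snr=2.0, window=(100.0, 400.0))
    return generate_meg_dataset(behavior, spec, n_sensors=24, noise_sd=0.0,
                                seed=5, epoch_ms=(-200.0, 600.0))


@pytest.fixture(scope="session")
def noisy_graded(behavior) -> "object":
    """SNR-1 abstract-graded recording on a short epoch."""
    spec = EmbeddingSpec("abstract_graded", snr=1.0, window=(100.0, 400.0))
    return generate_meg_dataset(behavior, spec, n_sensors=24, noise_sd=1.0,
                                seed=7, epoch_ms=(-200.0, 600.0))
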