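import numpy as np
import pytest

from piter.synth import SynthConfig, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """10 patients x 2 slides x 5 patches, 32 px — structural checks only."""
    cfg = SynthConfig(
        n_patients=10,
        slides_per_patient=2,
        patches_per_slide=5,
        patch_px=32,
        signal_strength=1.0,
        confound_strength=0.5,
        confound_label_corr={"train": 0.9, "val": 0.0},
        split_fractions={"train": 0.5, "val": 0.5},
        seed=42,
    )
    return generate_cohort(cfg)
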