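import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from vacquant.features import FeatureConfig, build_feature_stack
from vacquant.segmentation import (
    RandomForestConfig,
    extract_training_set,
    train_classifier,
)
from vacquant.synthetic import SectionSpec, generate_section, sample_scribbles


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


#: small scale set used where full default stacks would be wasteful
FAST_CONFIG = FeatureConfig(sigmas=(1.0, 2.0, 4.0), membrane_kernel_size=9,
                            membrane_rotations=8)


@pytest.fixture(scope="session")
def fast_config():
    return FAST_CONFIG


@pytest.fixture(scope="session")
def small_section():
    """One deterministic synthetic section with ~10% vacuolation."""
    spec = SectionSpec(canvas=(96, 128), target_vacuole_fraction=0.10,
                       vacuole_size_range=(3.0, 10.0), seed=7)
    return generate_section(spec)


@pytest.fixture(scope="session")
def small_model(small_section, fast_config):
    """A quick classifier trained on two small sections (for wiring tests)."""
    rng = np.random.default_rng(11)
    stacks, anns = {}, []
    for i in range(2):
        spec = SectionSpec(canvas=(96, 128), target_vacuole_fraction=0.10,
                           vacuole_size_range=(3.0, 10.0), seed=30 + i)
        image, truth = generate_section(spec)
        iid = f"small{i}"
        stacks[iid] = build_feature_stack(image, fast_config)
        anns += sample_scribbles(iid, truth, rng, n_annotations=6)
    samples, targets = extract_training_set(stacks, anns)
    return train_classifier(
        samples, targets,
        RandomForestConfig(n_trees=50, seed=3),
        fast_config,
    )
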