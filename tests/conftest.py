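import numpy as np
import pytest

from tripledare import GeneratorConfig, featurize_dataset, generate_dataset

SMALL_LABELS = ["jogging", "sitting", "sleeping", "stairs_up", "typing", "walking",
                "phone_in_hand", "phone_in_pocket"]


def small_generator_config(**overrides) -> GeneratorConfig:
    """A fast generator config: 2-s windows at 25 Hz, 8 labels."""
    defaults = dict(n_source=120, n_target=120, n_subjects_per_domain=6,
                    window_seconds=2.0, label_names=list(SMALL_LABELS),
                    shift_magnitude=1.0, target_label_noise=0.0, seed=0)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_pair():
    """A small featurized source/target pair shared across tests (read-only)."""
    cfg = small_generator_config()
    source = generate_dataset(cfg, "source")
    target = generate_dataset(cfg, "target")
    featurize_dataset(source)
    featurize_dataset(target)
    return cfg, source, target


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
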