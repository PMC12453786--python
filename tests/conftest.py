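import numpy as np
import pandas as pd
import pytest

from rheumkit import preprocess, synth
from rheumkit.synth import ClassProfile, GeneratorConfig


def scaled_default_config(scale: float, seed: int = 0) -> GeneratorConfig:
    """Default cohort with every class count multiplied by ``scale``."""
    cfg = synth.default_config(seed=seed)
    profiles = tuple(
        ClassProfile(p.label, max(int(round(p.n * scale)), 20), dict(p.shifts))
        for p in cfg.class_profiles
    )
    return GeneratorConfig(cfg.feature_specs, profiles, seed=seed)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 10%-scale default cohort with missingness injected (1,208 rows)."""
    cfg = scaled_default_config(0.1, seed=11)
    table = synth.generate_cohort(cfg)
    return synth.inject_missingness(table, cfg.feature_specs, seed=12)


@pytest.fixture(scope="session")
def small_encoded(small_cohort):
    """Imputed + encoded version of the small cohort, with labels."""
    filled, _ = preprocess.impute(small_cohort)
    X, y = preprocess.encode(filled)
    return X, y


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The full 12,085-row default cohort with missingness injected."""
    cfg = synth.default_config(seed=1)
    table = synth.generate_cohort(cfg)
    return synth.inject_missingness(table, cfg.feature_specs, seed=2)
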