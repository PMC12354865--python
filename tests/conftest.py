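import numpy as np
import pytest

from wsisurv.model import ModelConfig
from wsisurv.synth import SynthCohortSpec
from wsisurv.training import TrainConfig

# Desk-scale study conditions used across training/attribution tests: a
# 200-patient cohort with a strong planted tile signal, and a reduced-width
# model. Cohort and recipe are fixed here once so every test sees the same
# conditions.
SIGNAL_COHORT = dict(n_patients=200, feature_dim=16, tiles_per_patient_range=(40, 80),
                     signal_shift=4.0, signal_fraction=0.3, log_hr_per_risk_unit=2.5,
                     baseline_hazard=0.02, censoring_rate=0.015)

SMALL_MODEL = dict(input_dim=16, embed_dim=32, n_layers=2, n_heads=4, ffn_dim=64,
                   dropout=0.1, head_hidden=(16,), seed=0)

TRAIN_RECIPE = dict(tiles_per_bag=64, batch_size=64, lr=3e-3, max_epochs=40,
                    patience=15, seed=0)


@pytest.fixture(scope="session")
def signal_cohort_spec():
    return SynthCohortSpec(latent_risk="continuous", seed=1, **SIGNAL_COHORT)


@pytest.fixture(scope="session")
def small_model_cfg():
    return ModelConfig(**SMALL_MODEL)


@pytest.fixture(scope="session")
def train_recipe():
    return TrainConfig(**TRAIN_RECIPE)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_model():
    """A tiny 2-layer model for fast exact-arithmetic checks."""
    from wsisurv.model import MILRiskModel

    cfg = ModelConfig(input_dim=6, embed_dim=8, n_layers=2, n_heads=2, ffn_dim=12,
                      dropout=0.0, head_hidden=(5,), seed=3)
    return MILRiskModel(cfg)
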