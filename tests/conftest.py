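"""Shared fixtures: configs and a session-scoped trained count model.

Training even a small CNN dominates the suite's runtime, so one moderately
trained count model (2,500 crops, 8 epochs) is shared across the tests that
need plausible predictions; tests that probe training behaviour itself train
their own tiny models.
"""

from __future__ import annotations

from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from dropscreen.config import ExperimentConfig, KillingModel, RenderConfig, TrainingConfig
from dropscreen.datasets import make_crop_dataset
from dropscreen.models import accuracy_report, train_cellcount_model

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def render_config() -> RenderConfig:
    return RenderConfig()


@pytest.fixture(scope="session")
def killing_model() -> KillingModel:
    return KillingModel()


@pytest.fixture(scope="session")
def experiment_config() -> ExperimentConfig:
    return ExperimentConfig()


@pytest.fixture(scope="session")
def trained_count_setup():
    """A count model trained at reduced scale, plus its held-out evaluation."""
    ds = make_crop_dataset(3000, seed=101)
    cfg = TrainingConfig(epochs=8, seed=7)
    model = train_cellcount_model(ds.crops[:2500], ds.counts[:2500], cfg)
    pred = model.predict_counts_array(ds.crops[2500:])
    overall, stratified = accuracy_report(pred, ds.counts[2500:], cfg.c_max)
    return SimpleNamespace(
        model=model,
        config=cfg,
        dataset=ds,
        heldout_pred=pred,
        heldout_true=ds.counts[2500:],
        overall=overall,
        stratified=stratified,
    )
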