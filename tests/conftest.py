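import numpy as np
import pytest
from scipy.stats import binom

import cissacsp as cc


def chance_band(n_trials: int, coverage: float = 0.99) -> tuple[float, float]:
    """Central binomial interval around 50% accuracy, in percent."""
    lo, hi = binom.interval(coverage, n_trials, 0.5)
    return 100.0 * lo / n_trials, 100.0 * hi / n_trials


def small_synth(**overrides) -> cc.SynthConfig:
    """A scaled-down generator configuration for fast property tests."""
    base = dict(
        n_trials_per_class=30,
        n_channels=8,
        fs=100.0,
        trial_length=3.5,
        erd_depth=0.7,
        snr=1.0,
        seed=0,
    )
    base.update(overrides)
    return cc.SynthConfig(**base)


def small_pipeline(**overrides) -> cc.PipelineConfig:
    base = dict(fusion="pca", k=6, folds=5, seed=0)
    base.update(overrides)
    return cc.PipelineConfig(**base)


@pytest.fixture(scope="session")
def public_like():
    """The default-condition dataset: 280 trials, 17 channels, seed 7."""
    return cc.generate(cc.default_public_like())


@pytest.fixture(scope="session")
def default_cv_report(public_like):
    ts, _ = public_like
    cfg = cc.PipelineConfig(fusion="pca", k=12, seed=1)
    return cc.run_cv(ts, cfg)


@pytest.fixture(scope="session")
def default_features(public_like):
    """Full 96-column feature table of the default dataset (banks on all trials)."""
    ts, _ = public_like
    return cc.extract_features(ts, cc.PipelineConfig(seed=1))


@pytest.fixture
def balanced_labels():
    return np.concatenate([np.ones(140, dtype=int), np.full(140, 2)])


@pytest.fixture
def tiny_trialset():
    rng = np.random.default_rng(42)
    return cc.TrialSet(
        data=rng.standard_normal((8, 3, 40)),
        labels=np.array([1, 1, 1, 1, 2, 2, 2, 2]),
        fs=40.0,
        channel_names=["C3", "Cz", "C4"],
    )
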