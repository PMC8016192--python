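import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from allostate.featurize import FEATURE_COLUMNS
from allostate.synthetic import (MixtureComponent, MixtureSpec, ToyDimerSpec,
                                 default_anchor_mixtures)

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


def make_single_gaussian_mixtures(mu_a: float = 0.0, mu_i: float = 2.0,
                                  sd: float = 1.0) -> MixtureSpec:
    """One Gaussian per class-feature: the GNB-correct generating model."""
    c = MixtureComponent
    spec = MixtureSpec(components={
        "A": [[c(1.0, mu_a, sd)] for _ in FEATURE_COLUMNS],
        "I": [[c(1.0, mu_i, sd)] for _ in FEATURE_COLUMNS],
    })
    spec.validate()
    return spec


def make_separated_mixtures(gap_sds: float = 8.0) -> MixtureSpec:
    """Anchors separated far beyond their spread: Bayes error ~ 0."""
    return make_single_gaussian_mixtures(0.0, gap_sds, 1.0)


def labeled_frame(X: np.ndarray, labels) -> pd.DataFrame:
    df = pd.DataFrame(np.asarray(X, dtype=float),
                      columns=list(FEATURE_COLUMNS))
    df["label"] = labels
    return df


@pytest.fixture
def anchor_mixtures() -> MixtureSpec:
    return default_anchor_mixtures()


@pytest.fixture
def separated_mixtures() -> MixtureSpec:
    return make_separated_mixtures()


@pytest.fixture
def gaussian_mixtures() -> MixtureSpec:
    return make_single_gaussian_mixtures()


@pytest.fixture
def toy_spec() -> ToyDimerSpec:
    return ToyDimerSpec(rng_seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
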