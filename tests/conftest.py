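import numpy as np
import pytest

from vinepix.classifier import ClassRegistry
from vinepix.color_model import (
    CovarianceMatrix,
    PixelSample,
    ReferenceClass,
    fit_reference_class,
)


def sampled_class(name, mean, rng, n=40, sd=5.0, shrinkage=0.1, roles=()):
    """Fit a reference class from Gaussian draws around ``mean``."""
    px = np.clip(np.rint(rng.normal(mean, sd, size=(n, 3))), 0, 255)
    return fit_reference_class(name, PixelSample(px), shrinkage=shrinkage, roles=roles)


def exact_class(name, mean, S=None, roles=(), index=0):
    """A reference class with an exactly specified covariance (no fitting)."""
    S = np.eye(3) if S is None else np.asarray(S, dtype=np.float64)
    mean = np.asarray(mean, dtype=np.float64)
    sample = PixelSample(np.clip(np.tile(mean, (4, 1)), 0, 255))
    cov = CovarianceMatrix(S=S, means=mean, n_source=4, shrinkage=0.0)
    return ReferenceClass(
        name=name,
        sample=sample,
        means=mean,
        S=cov,
        S_inv=np.linalg.inv(S),
        index=index,
        roles=tuple(roles),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def four_class_registry(rng):
    """Background / wood / grape / leaf registry with well-separated colours."""
    return ClassRegistry(
        [
            sampled_class("Background", (235, 235, 235), rng, roles=("background",)),
            sampled_class("Wood", (105, 75, 45), rng),
            sampled_class("Grape", (50, 45, 75), rng, roles=("grape",)),
            sampled_class("Leaves", (80, 140, 60), rng, roles=("leaf",)),
        ]
    )
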