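"""Shared fixtures: synthetic patch pool and one trained desk regressor.

The desk model is trained once per session on severity-labeled synthetic
patches (the parameter-recovery setting) and reused by every test that
needs a content-sensitive regressor; stub models cover the tests that
only exercise plumbing.
"""

from __future__ import annotations

import numpy as np
import pytest

from pleoscore.config import RegressorConfig
from pleoscore.evaluation import make_patch_dataset
from pleoscore.regressor import PleomorphismRegressor


@pytest.fixture(scope="session")
def patch_pool():
    """2750 severity-labeled 64-px patches from 50 homogeneous ROIs."""
    X, y, roi_ids = make_patch_dataset(50, 55, seed=11)
    return X, y, roi_ids


@pytest.fixture(scope="session")
def patch_split(patch_pool):
    """Group-respecting split: ROIs 0-39 train, 40-49 held out."""
    X, y, roi_ids = patch_pool
    train = roi_ids < 40
    test = ~train
    return ((X[train], y[train]), (X[test], y[test]))


@pytest.fixture(scope="session")
def desk_model(patch_split):
    """Desk regressor trained on generating-severity targets."""
    (Xtr, ytr), _ = patch_split
    est = PleomorphismRegressor(config=RegressorConfig.desk(seed=0))
    est.fit(Xtr, ytr)
    return est


class StubNet:
    """Constant-output stand-in exposing the network surface."""

    def __init__(self, value: float, input_size: int = 64):
        self.value = float(value)
        self.config = RegressorConfig.desk(input_size=input_size)

    def forward(self, x):
        return np.full(len(x), self.value)

    def param_layers(self):
        return []

    def zero_grad(self):
        pass

    def backward(self, dout, capture_block=None):
        return None

    def get_weights(self):
        return []

    def set_weights(self, weights):
        pass


@pytest.fixture
def constant_net():
    return StubNet(2.0)
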