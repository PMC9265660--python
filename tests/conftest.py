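import numpy as np
import pytest

from ebmdea import PanelDataset, toy_fixture


@pytest.fixture
def toy_panel():
    return toy_fixture()


@pytest.fixture
def random_panel_factory():
    """Small random panels with positive inputs/outputs and no bad outputs."""

    def make(J=5, T=2, m=2, s=1, seed=0, with_bad=False, with_env=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(1.0, 10.0, size=(J, T, m))
        Y = rng.uniform(1.0, 10.0, size=(J, T, s))
        B = rng.uniform(1.0, 5.0, size=(J, T, 1)) if with_bad \
            else np.zeros((J, T, 0))
        Z = rng.normal(0, 1, size=(J, T, with_env))
        W = Y[:, :, 0]
        return PanelDataset(
            dmu_ids=[f"U{j}" for j in range(J)],
            periods=list(range(2000, 2000 + T)),
            X=X, Y=Y, B=B, Z=Z, W=W,
        )

    return make
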