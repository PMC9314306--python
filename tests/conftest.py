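import warnings

import numpy as np
import pytest

from promirt.grm import ItemParams
from promirt.icf import GradedResponseIRT
from promirt.longitudinal import LatentTrajectoryNLME
from promirt.simulate import TrialDesign, default_item_params, generate_trial


@pytest.fixture(scope="session")
def toy_items():
    """Three small items with mixed category counts."""
    return [
        ItemParams(1, 1.3, np.array([-0.5, 0.4, 1.2])),
        ItemParams(2, 0.9, np.array([0.0, 1.0])),
        ItemParams(3, 2.0, np.array([-1.0, 0.2, 0.9, 1.8])),
    ]


@pytest.fixture(scope="session")
def ers_items():
    return default_item_params()


@pytest.fixture(scope="session")
def small_trial():
    """A compact two-arm weekly trial reused across the suite."""
    design = TrialDesign(n_per_arm=(60, 60), schedule="weekly")
    return generate_trial(design, seed=3)


@pytest.fixture(scope="session")
def icf_fit_small(small_trial):
    return GradedResponseIRT(n_quadrature=15, compute_se=False, max_iter=250).fit(small_trial)


@pytest.fixture(scope="session")
def theta_small(icf_fit_small, small_trial):
    return icf_fit_small.transform(small_trial)


@pytest.fixture(scope="session")
def nlme_small(theta_small):
    # diagonal IIV keeps the observed information well conditioned at this size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return LatentTrajectoryNLME(corr_pairs={}, compute_se=True, max_iter=250).fit(theta_small)
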