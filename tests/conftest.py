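import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from histoharm.bags import Cohort, PatchBag
from histoharm.synthetic import AttributeSpec, SimulationConfig, simulate_cohort


def make_bag(slide_id, site, features, with_coords=True):
    features = np.asarray(features, dtype=float)
    coords = None
    if with_coords:
        import math
        P = features.shape[0]
        rows = max(1, int(math.floor(math.sqrt(P))))
        cols = int(math.ceil(P / rows))
        rc = np.arange(P)
        coords = np.column_stack([rc // cols, rc % cols])
    return PatchBag(slide_id=slide_id, site=site, features=features, coords=coords)


def make_cohort(bags, attributes=None):
    ids = [b.slide_id for b in bags]
    if attributes is None:
        attributes = pd.DataFrame(index=ids)
    return Cohort(bags=bags, attributes=attributes)


@pytest.fixture(scope="session")
def small_cohort():
    """2 sites x 20 slides x 50 patches, D=8, with clear batch effects."""
    cfg = SimulationConfig(
        n_sites=2, slides_per_site=20, patches_per_slide=50, n_features=8,
        additive_prior=[(-1.0, 0.5), (1.0, 0.5)],
        multiplicative_prior=(4.0, 3.0), seed=7,
    )
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def labeled_cohort():
    """4 sites, one separable binary attribute, small enough to train fast."""
    D = 16
    shifts = np.zeros((2, D))
    shifts[1, :4] = 2.0
    cfg = SimulationConfig(
        n_sites=4, slides_per_site=15, patches_per_slide=40, n_features=D,
        additive_prior=(0.0, 0.25), multiplicative_prior=(4.0, 3.0),
        attributes=[AttributeSpec("bio", 2, shifts, rho=0.0)], seed=21,
    )
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth
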