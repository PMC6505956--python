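import warnings

import numpy as np
import pandas as pd
import pytest

import tenurematch as tm
from tenurematch.schema import COVARIATES

warnings.filterwarnings("ignore", message="too few distinct matched controls")
warnings.filterwarnings("ignore", message="collinear bias-adjustment")


@pytest.fixture(scope="session")
def constant_effect_landscape():
    """Mid-size landscape with a constant protection effect of -0.05."""
    cfg = tm.LandscapeConfig(
        grid_width=220, grid_height=220, n_properties=320, seed=11,
        effect_curve_params={"kind": "constant", "value": -0.05})
    return tm.generate_landscape(cfg)


@pytest.fixture(scope="session")
def study_frame(constant_effect_landscape):
    """Estimation frame drawn from the constant-effect landscape."""
    return tm.build_frame(constant_effect_landscape.to_pixel_table(),
                          fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def question_a_estimate(study_frame):
    """A protected-vs-unprotected comparison with a feasible matched sample."""
    est = tm.run_comparison(
        study_frame.sample, tm.ComparisonSpec(question="A", biome="moist"),
        spillover_pool=study_frame.spillover_pool)
    assert not est.is_na
    return est


def make_hand_landscape():
    """2x3 landscape with hand-listed outcomes; top row protected."""
    cfg = tm.LandscapeConfig(grid_width=8, grid_height=8)  # config echo only
    h, w = 2, 3
    y = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.int8)
    y0 = np.array([[0, 0, 1], [1, 1, 0]], dtype=np.int8)
    protected = np.array([[True, True, True], [False, False, False]])
    covs = {c: np.zeros((h, w)) for c in COVARIATES}
    props = pd.DataFrame({
        "property_id": [0],
        "tenure": ["ejido"],
        "n_pixels": [6],
        "protected_fraction": [0.5],
    })
    return tm.SyntheticLandscape(
        config=cfg, covariates=covs,
        biome=np.full((h, w), "dry"),
        property_id=np.zeros((h, w), dtype=int),
        protected=protected, y=y, y0=y0, properties=props)


@pytest.fixture
def hand_landscape():
    return make_hand_landscape()
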