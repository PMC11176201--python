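"""Shared fixtures: reduced texture grids and reusable synthetic cohorts.

The expensive session fixtures (feature tables for ten texture-signal
cohorts and one null cohort) are shared between the selection, evaluation
and acceptance tests so each cohort is extracted once.
"""

from __future__ import annotations

import numpy as np
import pytest

from wallrad.feature_extraction import TextureConfig
from wallrad.feature_selection import SelectionConfig, obm_search
from wallrad.pipeline import cohort_feature_table
from wallrad.synthetic_cohort import ClinicalModel, SyntheticConfig, generate_cohort

# texture sweep used throughout the tests: 4 angles x 3 distances x
# 2 bin counts x 2 windows x 10 features = 480 texture columns,
# 509 columns in total with the other families
FAST_TEXTURE = TextureConfig(distances=(1, 2, 4), bins=(4, 8), windows=(5, 9))

# minimal sweep for tests that only need a handful of texture columns
TINY_TEXTURE = TextureConfig(
    angles_deg=(0.0, 90.0), distances=(1,), bins=(8,), windows=(5,),
    features=("contrast", "correlation"),
)

#: clinical model with no class differences at all (image-only contrast)
MATCHED_CLINICAL = ClinicalModel(prostate_mean=(45.0, 45.0), prostate_sd=(15.0, 15.0))

#: wrapper settings used for the subset searches in the tests
SEARCH_CFG = SelectionConfig(
    filter_pool_size=30, max_subset_size=5, wrapper_repeats=5, seed=7
)

SIGNAL_SEEDS = tuple(range(1, 11))
NULL_SEED = 11


def make_cohort_table(
    seed: int,
    texture_effect: float,
    n_negative: int = 23,
    n_positive: int = 17,
    texture_cfg: TextureConfig = FAST_TEXTURE,
    grid: tuple[int, int, int] = (40, 40, 40),
):
    """Cohort with class contrast only in wall texture (clinical matched)."""
    cfg = SyntheticConfig(
        n_negative=n_negative,
        n_positive=n_positive,
        grid_shape=grid,
        texture_effect=texture_effect,
        clinical_model=MATCHED_CLINICAL,
        seed=seed,
    )
    cases = generate_cohort(cfg)
    return cohort_feature_table(cases, texture_cfg)


@pytest.fixture(scope="session")
def signal_data():
    """Ten texture-signal cohorts (texture_effect=1.5, n=40), one per seed."""
    return [make_cohort_table(seed, texture_effect=1.5) for seed in SIGNAL_SEEDS]


@pytest.fixture(scope="session")
def signal_selections(signal_data):
    """Hybrid-search results on each signal cohort."""
    return [obm_search(table, labels, SEARCH_CFG) for table, labels in signal_data]


@pytest.fixture(scope="session")
def null_data():
    """One all-effects-zero cohort (n=40): classes exchangeable."""
    return make_cohort_table(NULL_SEED, texture_effect=0.0)
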