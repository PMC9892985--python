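import numpy as np
import pandas as pd
import pytest

from crowdkappa.io_core import RatingTable, validate_ratings
from crowdkappa.simulate import SimulationConfig, simulate_study
from crowdkappa.taxonomy import load_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


def make_table(rows, taxonomy=None, level=None) -> RatingTable:
    """Build a validated RatingTable from (rater, image, feature, present[,
    rt[, cohort]]) tuples."""
    records = []
    for row in rows:
        rater, image, feature, present = row[:4]
        rt = row[4] if len(row) > 4 else np.nan
        cohort = row[5] if len(row) > 5 else "crowd"
        records.append((rater, image, feature, present, rt, cohort))
    df = pd.DataFrame(
        records,
        columns=["rater_id", "image_id", "feature", "present", "reaction_time_s", "cohort"],
    )
    return validate_ratings(df, taxonomy=taxonomy, level=level)


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled simulation keeping the three-study structure."""
    return SimulationConfig(
        n_images=48,
        prevalence=0.4,
        n_panel_experts=20,
        substudies=4,
        panel_size=5,
        crowd_users=10,
        crowd_ratings_median=30,
        crowd_ratings_sigma=0.4,
        expert_crowd_size=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_study(small_config, seed=123)
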