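"""Shared fixtures: all test data is generated programmatically."""

import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from stratify.features import cohort_feature_table
from stratify.synthetic import default_cohort_spec, generate_cohort

# feature-index clipping and fat-pad flag warnings are expected on some
# random draws and are themselves under test elsewhere
logging.getLogger("stratify").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (133 animals, published group sizes)."""
    return generate_cohort(default_cohort_spec(seed=0))


@pytest.fixture(scope="session")
def default_feature_table(default_cohort):
    """Feature table of the default cohort (86 features per animal)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cohort_feature_table(default_cohort)


def gaussian_feature_table(
    n_per_group: int = 20,
    n_features: int = 6,
    informative: tuple = (0,),
    gap: float = 3.0,
    seed: int = 0,
    groups: tuple = (("A", "high"), ("B", "low")),
) -> pd.DataFrame:
    """Small synthetic feature table with planted informative columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, (name, label) in enumerate(groups):
        shift = gap if label == "high" else 0.0
        for i in range(n_per_group):
            feats = rng.normal(0.0, 1.0, n_features)
            for j in informative:
                feats[j] += shift
            row = {"animal_id": f"{name}_{i}", "group": name, "dll4_label": label}
            row.update({f"f{j}": feats[j] for j in range(n_features)})
            rows.append(row)
    return pd.DataFrame(rows)
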