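import numpy as np
import pandas as pd
import pytest

from spuritax import (
    SyntheticDesign,
    classify_by_label,
    simulate_study,
)


@pytest.fixture
def tiny_table():
    """2 taxa x 2 samples with counts [[5, 0], [1, 3]]."""
    return pd.DataFrame(
        [[5.0, 0.0], [1.0, 3.0]], index=["t1", "t2"], columns=["s1", "s2"]
    )


@pytest.fixture(scope="session")
def mock_study():
    """Default even 8-member mock, one run, triplicates (seed 0)."""
    return simulate_study(SyntheticDesign(seed=0))


@pytest.fixture(scope="session")
def mock_matches(mock_study):
    return classify_by_label(mock_study.ground_truth)


@pytest.fixture(scope="session")
def multirun_study():
    """Two replicate groups, three runs, run-specific contaminant pools."""
    design = SyntheticDesign(
        seed=7,
        n_true_taxa=20,
        profile="exponential",
        rank_ratio=0.85,
        n_runs=3,
        n_replicate_groups=2,
        replicates_per_group=3,
        group_profile_noise=0.2,
    )
    return simulate_study(design)


def random_count_table(rng, max_taxa=30, max_samples=5):
    """Random integer count table with positive sample sums."""
    n_taxa = int(rng.integers(1, max_taxa + 1))
    n_samples = int(rng.integers(1, max_samples + 1))
    counts = rng.integers(0, 2000, size=(n_taxa, n_samples)).astype(float)
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_taxa), j] = 1.0
    return pd.DataFrame(
        counts,
        index=[f"t{i}" for i in range(n_taxa)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
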