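import numpy as np
import pytest

from canfrag.fragdist import cohort_summary, normalize
from canfrag.synth import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def medium_cohort():
    """Desk-scale synthetic cohort: generator defaults except size/depth."""
    config = SyntheticCohortConfig(n_normal=12, n_tumor=9,
                                   fragments_per_sample=1_000_000, seed=101)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def medium_dists(medium_cohort):
    dists = [normalize(h) for h in medium_cohort.histograms]
    labels = list(medium_cohort.manifest["group"])
    return dists, labels


@pytest.fixture(scope="session")
def group_means(medium_cohort):
    """Cohort mean distribution per group."""
    means = {}
    for group in ("normal", "hemangiosarcoma"):
        dists = [normalize(h) for h in medium_cohort.group_histograms(group)]
        means[group] = cohort_summary(dists, group).mean_distribution()
    return means


def make_distribution(weights: dict[int, float], size_min: int = 74,
                      size_max: int = 439):
    """Build a distribution with mass at the given sizes (normalized)."""
    from canfrag.fragdist import FragmentSizeDistribution

    density = np.zeros(size_max - size_min + 1)
    for size, w in weights.items():
        density[size - size_min] = w
    return FragmentSizeDistribution("toy", density / density.sum(),
                                    size_min, size_max)
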