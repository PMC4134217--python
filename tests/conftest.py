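import pytest

from gsvc.classify import VECTOR_METHODS, loso_cv, mean_accuracy, vector_baselines
from gsvc.synthetic import SyntheticConfig, generate_dataset, variability_grid


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticConfig(sigma_pix=0.0, sigma_eta=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return generate_dataset(noiseless_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One canonical dataset at the default noise level."""
    return generate_dataset(SyntheticConfig(seed=5))


@pytest.fixture(scope="session")
def zero_overlap_datasets():
    """Twenty datasets at 0% middle-band overlap and no activation variability:
    the regime where the graph classifier should succeed and point-aligned
    vector classifiers should not."""
    return [ds for _, ds in variability_grid([0.0], [0.0], 20, seed=42, sigma_pix=0.5)]


@pytest.fixture(scope="session")
def zero_overlap_scores(zero_overlap_datasets):
    """Per-dataset LOSO mean accuracies of the graph classifier and every
    vector-based benchmark family on the zero-overlap suite."""
    rows = []
    for ds in zero_overlap_datasets:
        rec = {"gsvc": mean_accuracy(loso_cv(ds, q_per_subject=3))}
        for method in VECTOR_METHODS:
            rec[method], _ = vector_baselines(ds, method)
        rows.append(rec)
    return rows
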