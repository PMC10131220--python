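import numpy as np
import pytest

from gpcractivity import default_schema, make_toy_structures
from gpcractivity.model import LabeledDataset
from gpcractivity.synthetic import GeneratorConfig, make_feature_dataset


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def toy():
    """Five toy receptor frames spanning lambda 0..1 plus their BW map."""
    lams = np.linspace(0.0, 1.0, 5)
    frames, bwmap = make_toy_structures(lams)
    return frames, bwmap, lams


@pytest.fixture(scope="session")
def clean_dataset(schema):
    """Noise-free synthetic dataset: activity is an exact function of features."""
    cfg = GeneratorConfig(n_samples=400, sigma_feature=0.0, sigma_activity=0.0, seed=7)
    dataset, truth = make_feature_dataset(cfg, schema=schema)
    return dataset, truth


@pytest.fixture(scope="session")
def noisy_dataset(schema):
    cfg = GeneratorConfig(n_samples=600, seed=11)
    dataset, truth = make_feature_dataset(cfg, schema=schema)
    return dataset, truth


@pytest.fixture(scope="session")
def toy_trained(schema):
    """Model trained on featurized toy structures (activity = 100*lambda)."""
    from gpcractivity import featurize_frame
    from gpcractivity.model import StructureActivityModel
    from gpcractivity.synthetic import state_from_lam

    rng = np.random.default_rng(21)
    lams = rng.uniform(0.0, 1.0, 300)
    frames, bwmap = make_toy_structures(lams, jitter_sigma=0.05, seed=21)
    vecs = [featurize_frame(f, default_schema(), bwmap) for f in frames]
    dataset = LabeledDataset.from_vectors(vecs, state_from_lam(lams), 100.0 * lams)
    results = StructureActivityModel(dataset, "xgboost", seed=0).fit()
    return results, bwmap


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_dataset_from_lam(lam, schema, sigma_feature=0.0, sigma_activity=0.0, seed=0):
    cfg = GeneratorConfig(
        n_samples=len(lam), sigma_feature=sigma_feature,
        sigma_activity=sigma_activity, seed=seed,
    )
    return make_feature_dataset(cfg, schema=schema, lam=np.asarray(lam))
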