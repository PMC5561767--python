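import numpy as np
import pytest

from sipwelm import (
    FeatureMatrix,
    PSSM,
    SyntheticSpec,
    generate_dataset,
    lag_transform,
)
from sipwelm.pssm_io import PSIBLAST_COLUMN_ORDER


def random_pssm(L: int, seed: int, protein_id: str = "rand") -> PSSM:
    rng = np.random.default_rng(seed)
    return PSSM(
        protein_id=protein_id,
        scores=rng.normal(0.0, 3.0, size=(L, 20)),
        column_order=PSIBLAST_COLUMN_ORDER,
        source="synthetic",
    )


def dataset_to_features(data) -> FeatureMatrix:
    """LAG-transform a list of (PSSM, label) pairs into a FeatureMatrix."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vectors = [lag_transform(p) for p, _ in data]
    labels = {p.protein_id: lab for p, lab in data}
    return FeatureMatrix.from_vectors(vectors, labels)


@pytest.fixture(scope="session")
def separable_features() -> FeatureMatrix:
    """Strongly separable imbalanced LAG dataset (large shift, low noise)."""
    spec = SyntheticSpec(
        n_pos=25, n_neg=100, class_shift=5.0, noise_sd=1.0, seed=11
    )
    return dataset_to_features(generate_dataset(spec))


@pytest.fixture(scope="session")
def default_features() -> FeatureMatrix:
    """LAG dataset at the default (yeast-like 1:7.8) study conditions."""
    return dataset_to_features(generate_dataset(SyntheticSpec(seed=7)))
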