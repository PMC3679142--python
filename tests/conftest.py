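import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hetdimer as hd

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def fig2_toy():
    """Four-protein complex C1 with five internal interaction edges, one of
    which ({A, B}) is also catalogued as the heterodimer C2."""
    catalog = hd.ComplexCatalog({"C1": {"A", "B", "C", "D"}, "C2": {"A", "B"}})
    network = hd.WeightedPPINetwork.from_edges([
        ("A", "B", 5.0), ("A", "C", 4.0), ("B", "C", 3.0),
        ("B", "D", 2.0), ("C", "D", 6.0),
    ])
    return catalog, network


@pytest.fixture(scope="session")
def default_synthetic():
    """One draw of the default synthetic study conditions."""
    return hd.generate(hd.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_features(default_synthetic):
    """Feature matrix, labels and K_dc indicator for the default draw."""
    data = default_synthetic
    pairs = [ex.pair for ex in data.examples]
    features = hd.feature_matrix(data.network, data.domains, pairs)
    labels = np.array([ex.label for ex in data.examples])
    indicator = hd.kdc_gram(pairs, data.domains)
    return features, labels, indicator


def random_annotation(rng, proteins, n_domain_types=5, max_per=3, p_unannotated=0.0):
    """Random domain annotation over the given proteins (test helper)."""
    ann = hd.DomainAnnotation()
    for protein in proteins:
        if p_unannotated and rng.random() < p_unannotated:
            continue
        k = int(rng.integers(1, max_per + 1))
        for d in rng.integers(0, n_domain_types, size=k):
            ann.add(protein, f"d{d}")
    return ann
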