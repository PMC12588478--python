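"""Shared fixtures: small synthetic datasets generated at test time.

Expensive fixtures are session-scoped so the recovery, classification and
pipeline checks share one dataset instead of regenerating it per test.
"""

import logging

import numpy as np
import pytest

from coexcom import SyntheticConfig, generate_dataset
from coexcom.communities import CommunityRecord
from coexcom.network import build_network
from coexcom.preprocess import preprocess_pipeline

logging.getLogger("coexcom").setLevel(logging.ERROR)


def jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if a | b else 0.0


@pytest.fixture(scope="session")
def recovery_dataset():
    """Planted-partition benchmark: 6 modules x 20 genes + 60 background,
    rho = 0.8, n = 100, no class signal (pure module recovery)."""
    cfg = SyntheticConfig(
        n_genes=180, n_samples=100, n_case=40,
        module_sizes=(20,) * 6, within_module_correlation=0.8,
        discriminative_modules=(), effect_size=0.0,
        seed=1, n_batches=1, annotation_overlap=6, annotation_size=10)
    matrix, metadata, truth = generate_dataset(cfg)
    processed = preprocess_pipeline(matrix, metadata)
    graph = build_network(processed)
    return {"config": cfg, "matrix": matrix, "metadata": metadata,
            "truth": truth, "processed": processed, "graph": graph}


@pytest.fixture(scope="session")
def classification_dataset():
    """Two 30-gene modules, one with 10 informative genes at effect size 2,
    one pure noise; n = 200 balanced."""
    cfg = SyntheticConfig(
        n_genes=120, n_samples=200, n_case=100,
        module_sizes=(30, 30), within_module_correlation=0.5,
        discriminative_modules=(0,), effect_size=2.0,
        informative_fraction=1 / 3, seed=42, n_batches=1,
        annotation_overlap=6, annotation_size=10)
    matrix, metadata, truth = generate_dataset(cfg)
    processed = preprocess_pipeline(matrix, metadata)
    disc = CommunityRecord("disc", truth.module_genes(0), [0], True)
    null = CommunityRecord("null", truth.module_genes(1), [1], True)
    return {"config": cfg, "matrix": matrix, "metadata": metadata,
            "truth": truth, "processed": processed,
            "disc": disc, "null": null}


@pytest.fixture(scope="session")
def independent_dataset(classification_dataset):
    """Second draw from the same generating process (new seed): the
    independent validation cohort."""
    base = classification_dataset["config"]
    cfg = SyntheticConfig(**{**base.__dict__, "seed": base.seed + 1000})
    matrix, metadata, truth = generate_dataset(cfg)
    processed = preprocess_pipeline(matrix, metadata)
    return {"config": cfg, "metadata": metadata, "truth": truth,
            "processed": processed}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
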