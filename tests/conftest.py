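"""Shared fixtures: the synthetic benchmark and derived pipeline artifacts.

Heavy artifacts (identity matrix, sampled negatives, split, trained model)
are session-scoped so the many tests that need them pay their cost once.
"""

from __future__ import annotations

import numpy as np
import pytest

from esp.classifier import PairClassifier, assemble_features, predict_scores
from esp.enzyme_encoding import identity_profile_vectors
from esp.identity_split import SplitConfig, identity_matrix, make_split
from esp.molecule_features import fingerprints_for, pairwise_similarity
from esp.negative_sampling import SamplingConfig, sample_negatives
from esp.synthetic_data import SynthConfig, make_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """Default desk benchmark: dataset + hidden truth."""
    return make_benchmark(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def bench_fps(benchmark):
    dataset, _ = benchmark
    return fingerprints_for(dataset.molecules)


@pytest.fixture(scope="session")
def bench_sim(bench_fps):
    return pairwise_similarity(bench_fps)


@pytest.fixture(scope="session")
def bench_negatives(benchmark, bench_sim):
    dataset, _ = benchmark
    return sample_negatives(dataset.positives(), bench_sim,
                            SamplingConfig(seed=0))


@pytest.fixture(scope="session")
def bench_identities(benchmark):
    dataset, _ = benchmark
    return identity_matrix(dataset.enzymes)


@pytest.fixture(scope="session")
def bench_split(benchmark, bench_negatives, bench_identities):
    dataset, _ = benchmark
    negatives, _ = bench_negatives
    pairs = dataset.positives() + negatives
    return make_split(dataset.enzymes, pairs, SplitConfig(seed=0),
                      bench_identities)


@pytest.fixture(scope="session")
def bench_model(benchmark, bench_fps, bench_negatives, bench_split,
                bench_identities):
    """Trained classifier plus test-set scores on the default benchmark."""
    dataset, _ = benchmark
    negatives, _ = bench_negatives
    split = bench_split
    pairs = dataset.positives() + negatives
    evecs = identity_profile_vectors(dataset.enzymes, 3, bench_identities)
    fpd = {k: v.astype(np.float64) for k, v in bench_fps.items()}
    train = [p for p in pairs if split.partition[p.enzyme_id] == "train"]
    test = [p for p in pairs if split.partition[p.enzyme_id] == "test"]
    X_tr, y_tr, recipe = assemble_features(train, evecs, fpd)
    X_te, y_te, _ = assemble_features(test, evecs, fpd)
    model = PairClassifier(seed=0, n_estimators=300, max_depth=8)
    model.fit(X_tr, y_tr, recipe)
    scores = predict_scores(model, X_te)
    return {"model": model, "enzyme_vectors": evecs, "mol_vectors": fpd,
            "train_pairs": train, "test_pairs": test, "scores": scores,
            "labels": y_te, "recipe": recipe}
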