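"""Shared fixtures: packaged gene models and reference sequences, plus one
default simulated cohort reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from linumpool import calling, datasets, simulate


@pytest.fixture(scope="session")
def models():
    return datasets.load_fixture_gene_models()


@pytest.fixture(scope="session")
def by_id(models):
    return {m.gene_id: m for m in models}


@pytest.fixture(scope="session")
def references(models):
    return datasets.build_references(models)


@pytest.fixture(scope="session")
def default_cohort(models, references):
    """Default-condition cohort: 84 cultivars, 400x, error 0.005, seed 11."""
    config = simulate.CohortConfig()
    truth = simulate.simulate_truth(config, seed=11, models=models, references=references)
    counts = simulate.simulate_pool_counts(truth, seed=11)
    phenotypes = simulate.simulate_phenotypes(truth, seed=11)
    return truth, counts, phenotypes


@pytest.fixture(scope="session")
def consensus_calls(default_cohort):
    _truth, counts, _phenotypes = default_cohort
    calls_a = calling.call_variants_threshold(counts)
    calls_b = calling.call_variants_binomial(counts)
    return calling.filter_low_vaf(calling.consensus(calls_a, calls_b))


@pytest.fixture(scope="session")
def strata_cohort(models, references):
    """Low-noise three-strata cohort for clustering and classification."""
    config = simulate.CohortConfig.three_strata_demo()
    truth = simulate.simulate_truth(config, seed=11, models=models, references=references)
    counts = simulate.simulate_pool_counts(truth, seed=11)
    phenotypes = simulate.simulate_phenotypes(truth, seed=11)
    return truth, counts, phenotypes


def consensus_of(counts):
    calls_a = calling.call_variants_threshold(counts)
    calls_b = calling.call_variants_binomial(counts)
    return calling.filter_low_vaf(calling.consensus(calls_a, calls_b))


@pytest.fixture(scope="session")
def strata_consensus(strata_cohort):
    _truth, counts, _phenotypes = strata_cohort
    return consensus_of(counts)


def greedy_ward_oracle(matrix: np.ndarray):
    """Independent greedy Ward-D2 clustering: at every step merge the pair
    with the smallest sqrt(2|A||B|/(|A|+|B|)) * ||centroid_A − centroid_B||.

    Returns [(merge cost, frozenset of member indices), ...]."""
    import itertools

    clusters = {i: [i] for i in range(len(matrix))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            na, nb = len(clusters[a]), len(clusters[b])
            ca = matrix[clusters[a]].mean(axis=0)
            cb = matrix[clusters[b]].mean(axis=0)
            cost = np.sqrt(2 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
            if best is None or cost < best[0]:
                best = (cost, a, b)
        cost, a, b = best
        members = sorted(clusters.pop(a) + clusters.pop(b))
        clusters[min(a, b)] = members
        merges.append((cost, frozenset(members)))
    return merges


def dendrogram_merge_sets(dendro):
    """The (height, merged member set) sequence of a Dendrogram."""
    n = dendro.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, height, _size) in enumerate(dendro.merges()):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        merges.append((height, merged))
    return merges


def three_strata_labels(truth) -> np.ndarray:
    """Collapse strata to the clustering ground truth both/one/neither."""
    return np.where(
        np.isin(truth.strata, ["fad3a_only", "fad3b_only"]),
        "one",
        np.where(truth.strata == "both", "both", "neither"),
    )
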