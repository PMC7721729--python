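"""Shared fixtures: synthetic cohorts at two scales.

The *small* bundle (600 patients x 120 concepts, 4 leaves) backs fast unit
tests; the *mini* bundle (3,000 x 400, 6 leaves under 2 superclusters) and
a matched structureless null back the slower end-to-end recovery checks.
Heavy artifacts are session-scoped and derived deterministically from fixed
seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenoclust import (
    PatientConceptMatrix,
    aggregate_counts,
    filter_complaints,
    fit_kmeans,
    tfidf_transform,
)
from phenoclust.clustering import derive_seed
from phenoclust.synthetic import (
    default_vocabulary,
    generate_cohort,
    generate_null_cohort,
    paper_scale_mini,
    small_preset,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

MASTER_SEED = 11


def cohort_counts(mentions, meta, cohort) -> PatientConceptMatrix:
    vocab = default_vocabulary(cohort)
    return aggregate_counts(filter_complaints(mentions, vocab), meta)


def make_mini_bundle(seed: int) -> dict:
    pheno, cohort = paper_scale_mini(seed=seed)
    mentions, meta, truth = generate_cohort(pheno, cohort)
    counts = cohort_counts(mentions, meta, cohort)
    return {
        "pheno": pheno,
        "cohort": cohort,
        "meta": meta,
        "truth": truth.set_index("patient_id"),
        "counts": counts,
    }


@pytest.fixture(scope="session")
def small_bundle() -> dict:
    pheno, cohort = small_preset(seed=MASTER_SEED)
    mentions, meta, truth = generate_cohort(pheno, cohort)
    return {
        "pheno": pheno,
        "cohort": cohort,
        "mentions": mentions,
        "meta": meta,
        "truth": truth.set_index("patient_id"),
        "vocab": default_vocabulary(cohort),
        "counts": cohort_counts(mentions, meta, cohort),
    }


@pytest.fixture(scope="session")
def mini_bundle() -> dict:
    return make_mini_bundle(MASTER_SEED)


@pytest.fixture(scope="session")
def mini_tfidf(mini_bundle):
    counts, _ = mini_bundle["counts"].drop_zero_patients()
    return tfidf_transform(counts)


@pytest.fixture(scope="session")
def mini_truth_leaves(mini_bundle, mini_tfidf) -> pd.Series:
    return mini_bundle["truth"].loc[list(mini_tfidf.patient_index), "leaf"]


@pytest.fixture(scope="session")
def mini_k6(mini_tfidf):
    return fit_kmeans(mini_tfidf, 6, derive_seed(MASTER_SEED, 6))


@pytest.fixture(scope="session")
def mini_k2(mini_tfidf):
    return fit_kmeans(mini_tfidf, 2, derive_seed(MASTER_SEED, 2))


@pytest.fixture(scope="session")
def null_bundle() -> dict:
    _, cohort = paper_scale_mini(seed=MASTER_SEED + 1000)
    mentions, meta, truth = generate_null_cohort(cohort)
    counts = cohort_counts(mentions, meta, cohort)
    return {"cohort": cohort, "meta": meta, "truth": truth, "counts": counts}


@pytest.fixture(scope="session")
def null_tfidf(null_bundle):
    counts, _ = null_bundle["counts"].drop_zero_patients()
    return tfidf_transform(counts)


def random_count_matrix(rng: np.random.Generator, max_n: int = 10, max_c: int = 10):
    """Small random count matrix with no all-zero concept columns."""
    import scipy.sparse as sp

    n = int(rng.integers(2, max_n + 1))
    c = int(rng.integers(1, max_c + 1))
    counts = rng.integers(0, 5, size=(n, c))
    counts[0, :] = np.maximum(counts[0, :], 1)  # guarantee df >= 1
    return PatientConceptMatrix(
        patient_index=tuple(f"P{i}" for i in range(n)),
        concept_index=tuple(f"C{j:07d}" for j in range(c)),
        counts=sp.csr_matrix(counts),
    )
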