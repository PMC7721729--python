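"""Model/Results interface over the phenotype-discovery pipeline.

:class:`PhenotypeModel` is constructed from a patient-by-concept count
matrix (plus optional patient metadata) and holds the analysis
configuration; :meth:`PhenotypeModel.fit` runs vectorization, the K-means
sweep, bootstrap stability selection and dendrogram construction, returning
a :class:`PhenotypeResults` that exposes the estimates (partitions, stable
K values, the cluster tree), their stability diagnostics, per-cluster
enrichment/summary/association analyses and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import characterize, clustering, corpus, hierarchy, vectorize
from .characterize import AssociationReport, ClusterSummary, EnrichmentTable
from .clustering import ClusteringResult, StabilityReport
from .corpus import ConceptVocabulary, MentionRecord, PatientConceptMatrix
from .hierarchy import PhenotypeDendrogram
from .vectorize import TfidfMatrix


class PhenotypeModel:
    """Multiscale complaint-phenotype discovery for one cohort.

    Parameters
    ----------
    counts
        Aggregated patient x concept mention counts.  All-zero patients
        are excluded from the analysis (they carry no complaint
        representation); their ids are kept in ``excluded_patients``.
    metadata
        Optional per-patient table (age_years, sex, bmi, died_in_hospital,
        icd10_codes) used for cluster summaries.
    k_values
        The resolutions to sweep (default 2..30).
    tf, idf, norm
        TF-IDF variant switches (see :mod:`phenoclust.vectorize`).
    """

    def __init__(
        self,
        counts: PatientConceptMatrix,
        metadata: pd.DataFrame | None = None,
        *,
        k_values: Sequence[int] = tuple(range(2, 31)),
        tf: str = "raw",
        idf: str = "smooth",
        norm: str = "l2",
        n_init: int = clustering.DEFAULT_N_INIT,
        max_iter: int = clustering.DEFAULT_MAX_ITER,
        tol: float = clustering.DEFAULT_TOL,
    ) -> None:
        counts, excluded = counts.drop_zero_patients()
        self.counts = counts
        self.excluded_patients = excluded
        if metadata is not None:
            corpus.validate_metadata(metadata)
            missing = [p for p in counts.patient_index if p not in metadata.index]
            if missing:
                raise ValueError(f"metadata missing patients: {missing[:10]}")
            metadata = metadata.loc[list(counts.patient_index)]
        self.metadata = metadata
        self.k_values = tuple(k_values)
        self.tf, self.idf_variant, self.norm = tf, idf, norm
        self.n_init, self.max_iter, self.tol = n_init, max_iter, tol

    @classmethod
    def from_mentions(
        cls,
        mentions: Sequence[MentionRecord],
        metadata: pd.DataFrame,
        vocab: ConceptVocabulary,
        on_unknown: str = "warn",
        **kwargs,
    ) -> "PhenotypeModel":
        """Build the model from raw mention records: filter to
        positively-asserted complaints, then aggregate counts."""
        complaints = corpus.filter_complaints(mentions, vocab, on_unknown=on_unknown)
        counts = corpus.aggregate_counts(complaints, metadata)
        return cls(counts, metadata=metadata, **kwargs)

    @property
    def exog_names(self) -> tuple[str, ...]:
        return self.counts.concept_index

    def fit(
        self,
        *,
        seed: int = 0,
        n_bootstrap: int = clustering.DEFAULT_N_BOOTSTRAP,
        stability_threshold: float = clustering.DEFAULT_STABILITY_THRESHOLD,
        bootstrap_n_init: int = clustering.DEFAULT_BOOTSTRAP_N_INIT,
        stability: bool = True,
    ) -> "PhenotypeResults":
        """Run the sweep (and, unless ``stability=False``, the bootstrap
        stability selection and dendrogram) and return the results."""
        X = vectorize.tfidf_transform(
            self.counts, tf=self.tf, norm=self.norm, idf_variant=self.idf_variant
        )
        clusterings = clustering.sweep_kmeans(
            X, self.k_values, seed,
            n_init=self.n_init, max_iter=self.max_iter, tol=self.tol,
        )
        reports: dict[int, StabilityReport] = {}
        stable_k: list[int] = []
        dendrogram = None
        if stability:
            for K in self.k_values:
                reports[K] = clustering.bootstrap_stability(
                    X, clusterings[K], B=n_bootstrap,
                    seed=clustering.derive_seed(seed, 7, K),
                    threshold=stability_threshold, n_init=bootstrap_n_init,
                )
            stable_k = clustering.select_stable(list(reports.values()))
            if stable_k:
                dendrogram = hierarchy.build_dendrogram(
                    {K: clusterings[K] for K in stable_k}, X.patient_index
                )
        return PhenotypeResults(
            model=self,
            tfidf=X,
            clusterings=clusterings,
            stability_reports=reports,
            stable_k=tuple(stable_k),
            dendrogram=dendrogram,
            seed=seed,
        )


@dataclass
class PhenotypeResults:
    """Fitted multiscale phenotype structure plus diagnostics."""

    model: PhenotypeModel
    tfidf: TfidfMatrix
    clusterings: dict[int, ClusteringResult]
    stability_reports: dict[int, StabilityReport]
    stable_k: tuple[int, ...]
    dendrogram: PhenotypeDendrogram | None
    seed: int
    _enrichment_cache: dict = field(default_factory=dict, repr=False)

    @property
    def patient_index(self) -> tuple[str, ...]:
        return self.tfidf.patient_index

    def labels(self, K: int) -> np.ndarray:
        return self.clusterings[K].labels

    # -- characterization ---------------------------------------------------

    def enrichment_tables(self, K: int, equal_var: bool = False) -> list[EnrichmentTable]:
        """Per-cluster concept enrichment at resolution K.  The Bonferroni
        family is (concepts tested) x (clusters at this K)."""
        key = (K, equal_var)
        if key not in self._enrichment_cache:
            m = len(self.tfidf.concept_index) * K
            self._enrichment_cache[key] = [
                characterize.enrich_cluster(
                    self.tfidf, self.labels(K), cid, m,
                    counts=self.model.counts, equal_var=equal_var,
                )
                for cid in range(K)
            ]
        return self._enrichment_cache[key]

    def top_concepts(
        self, K: int, n: int = characterize.DEFAULT_TOP_N,
        alpha: float = characterize.DEFAULT_ALPHA,
    ) -> dict[int, list[str]]:
        return {
            t.cluster_id: characterize.top_concepts(t, n=n, alpha=alpha)
            for t in self.enrichment_tables(K)
        }

    def cluster_summaries(self, K: int, **kwargs) -> list[ClusterSummary]:
        if self.model.metadata is None:
            raise ValueError("model was built without patient metadata")
        return [
            characterize.cluster_summary(self.model.metadata, self.labels(K), cid, **kwargs)
            for cid in range(K)
        ]

    def association(
        self, K: int, n: int = characterize.DEFAULT_TOP_N,
        alpha: float = characterize.DEFAULT_ALPHA,
        presence: Mapping[str, frozenset] | None = None,
    ) -> AssociationReport:
        """Concept association analysis over the top-n enriched concepts of
        every cluster at K (within- vs between-cluster comparison)."""
        return characterize.association_analysis(
            self.model.counts, self.top_concepts(K, n=n, alpha=alpha), presence=presence
        )

    # -- reporting ----------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for K in self.model.k_values:
            res = self.clusterings[K]
            rep = self.stability_reports.get(K)
            rows.append(
                {
                    "K": K,
                    "inertia": res.inertia,
                    "min_cluster_size": int(res.cluster_sizes.min()),
                    "min_stability": rep.min_stability if rep else float("nan"),
                    "mean_stability": float(rep.per_cluster_stability.mean()) if rep else float("nan"),
                    "stable": rep.stable if rep else False,
                }
            )
        return pd.DataFrame(rows).set_index("K")

    def summary(self) -> str:
        """Human-readable fit report."""
        n, c = self.tfidf.shape
        frame = self.summary_frame()
        lines = [
            "Multiscale complaint-phenotype discovery",
            "=" * 46,
            f"Patients: {n}    Concepts: {c}    Seed: {self.seed}",
            f"TF-IDF: tf={self.model.tf}, idf={self.model.idf_variant}, norm={self.model.norm}",
            f"K sweep: {list(self.model.k_values)}",
            f"Stable K: {list(self.stable_k) if self.stable_k else 'none'}",
            "",
            frame.to_string(
                float_format=lambda v: f"{v:.4f}", columns=frame.columns
            ),
        ]
        if self.dendrogram is not None:
            lines += ["", "Dendrogram (Newick): " + hierarchy.to_newick(self.dendrogram)]
        return "\n".join(lines)
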