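"""Enrichment testing, descriptive summaries and association scores."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st

from phenoclust import (
    PatientConceptMatrix,
    association_analysis,
    association_score,
    bonferroni_adjust,
    cluster_summary,
    enrich_cluster,
    top_concepts,
)
from phenoclust.characterize import EnrichmentTable
from phenoclust.vectorize import TfidfMatrix


def tfidf_from(values):
    arr = np.asarray(values, dtype=float)
    return TfidfMatrix(
        patient_index=tuple(f"P{i}" for i in range(arr.shape[0])),
        concept_index=tuple(f"C{j:07d}" for j in range(arr.shape[1])),
        values=arr,
        normalized=False,
    )


class TestBonferroni:
    def test_worked_examples(self):
        assert bonferroni_adjust(0.01, 10) == pytest.approx(0.1)
        assert bonferroni_adjust(0.5, 4) == 1.0
        assert bonferroni_adjust(0.37, 1) == 0.37

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            bonferroni_adjust(1.5, 2)
        with pytest.raises(ValueError, match="family size"):
            bonferroni_adjust(0.5, 0)

    @given(st.floats(0, 1), st.integers(1, 10**6))
    def test_capped_and_monotone(self, p, m):
        adj = bonferroni_adjust(p, m)
        assert 0 <= adj <= 1
        assert adj >= min(1.0, p)


class TestEnrichCluster:
    def test_strong_signal_yields_tiny_p(self):
        # concept 0 nonzero only inside the 50-patient cluster
        rng = np.random.default_rng(0)
        values = rng.random((100, 3)) * 0.05
        values[:50, 0] += 5.0
        labels = np.array([0] * 50 + [1] * 50)
        table = enrich_cluster(tfidf_from(values), labels, 0, m=3).table
        assert table.loc[0, "p_raw"] < 1e-6
        assert table.loc[0, "prevalence_in"] == 1.0

    def test_matches_independent_reference_ttest(self):
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            values = rng.random((n, 4))
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.sum() < 2 or (1 - labels).sum() < 2:
                continue
            table = enrich_cluster(tfidf_from(values), labels, 1, m=4).table
            for j in range(4):
                _, p_ref, _ = sm_ttest(
                    values[labels == 1, j], values[labels == 0, j],
                    alternative="larger", usevar="unequal",
                )
                assert table.loc[j, "p_raw"] == pytest.approx(p_ref, abs=1e-10)

    def test_constant_concept_gets_p_one(self):
        values = np.ones((10, 2))
        values[:, 1] = np.arange(10.0)
        labels = np.array([0] * 5 + [1] * 5)
        table = enrich_cluster(tfidf_from(values), labels, 0, m=2).table
        assert table.loc[0, "t_statistic"] == 0.0
        assert table.loc[0, "p_adjusted"] == 1.0

    def test_degenerate_cluster_sizes_rejected(self):
        values = np.random.default_rng(0).random((4, 2))
        with pytest.raises(ValueError, match=">= 2 members"):
            enrich_cluster(tfidf_from(values), np.array([0, 1, 1, 1]), 0, m=2)

    def test_prevalences_come_from_counts_when_given(self):
        counts = PatientConceptMatrix(
            patient_index=("P0", "P1", "P2", "P3"),
            concept_index=("C0000000",),
            counts=sp.csr_matrix(np.array([[2], [0], [1], [0]])),
        )
        values = np.array([[0.9], [0.0], [0.4], [0.0]])
        labels = np.array([0, 0, 1, 1])
        table = enrich_cluster(tfidf_from(values), labels, 0, m=1, counts=counts).table
        assert table.loc[0, "prevalence_in"] == 0.5
        assert table.loc[0, "prevalence_out"] == 0.5

    def test_monotone_in_signal(self):
        # raising in-cluster values never increases the raw p-value
        rng = np.random.default_rng(1)
        values = rng.random((40, 1))
        labels = np.array([0] * 20 + [1] * 20)
        p_prev = 1.1
        for bump in (0.0, 0.5, 1.0, 2.0):
            v = values.copy()
            v[labels == 0, 0] += bump
            p = enrich_cluster(tfidf_from(v), labels, 0, m=1).table.loc[0, "p_raw"]
            assert p <= p_prev + 1e-12
            p_prev = p


class TestTopConcepts:
    @staticmethod
    def table_from(rows):
        t = pd.DataFrame(rows, columns=["concept_id", "t_statistic", "p_raw", "p_adjusted"])
        return EnrichmentTable(cluster_id=0, table=t, family_size=len(t))

    def test_all_significant_returned_in_p_order(self):
        t = self.table_from([("A", 3.0, 0.002, 0.02), ("B", 5.0, 0.0005, 0.005),
                             ("C", 2.0, 0.004, 0.04)])
        assert top_concepts(t, n=10, alpha=0.05) == ["B", "A", "C"]

    def test_none_significant_empty(self):
        t = self.table_from([("A", 1.0, 0.2, 1.0)])
        assert top_concepts(t, n=10, alpha=0.05) == []

    def test_ties_broken_by_t_then_id(self):
        t = self.table_from([("B", 2.0, 0.001, 0.01), ("A", 2.0, 0.001, 0.01),
                             ("C", 9.0, 0.001, 0.01)])
        assert top_concepts(t, n=2, alpha=0.05) == ["C", "A"]

    def test_truncates_to_n(self):
        t = self.table_from([(f"C{i}", 1.0, 0.001 * (i + 1), 0.01 * (i + 1))
                             for i in range(5)])
        assert len(top_concepts(t, n=3, alpha=0.5)) == 3


class TestClusterSummary:
    @staticmethod
    def meta_from(ages, sexes=None, bmis=None, died=None, icd=None):
        n = len(ages)
        return pd.DataFrame(
            {
                "age_years": ages,
                "sex": sexes or ["F"] * n,
                "bmi": bmis or [25.0] * n,
                "died_in_hospital": died or [False] * n,
                "icd10_codes": icd or [frozenset({"I50"})] * n,
            },
            index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"),
        )

    def test_interpolated_quartiles(self):
        meta = self.meta_from([50.0, 60.0, 70.0])
        s = cluster_summary(meta, np.zeros(3, int), 0)
        assert (s.age_median, s.age_q25, s.age_q75) == (60.0, 55.0, 65.0)

    def test_all_female_cluster(self):
        meta = self.meta_from([40.0, 41.0], sexes=["F", "F"])
        assert cluster_summary(meta, np.zeros(2, int), 0).fraction_female == 1.0

    def test_no_deaths_zero_mortality(self):
        meta = self.meta_from([40.0, 41.0])
        assert cluster_summary(meta, np.zeros(2, int), 0).in_hospital_mortality_fraction == 0.0

    def test_icd_floor_filters_rare_codes(self):
        icd = [frozenset({"I50"})] * 19 + [frozenset({"I50", "Q24"})]
        meta = self.meta_from([50.0] * 20, icd=icd)
        s = cluster_summary(meta, np.zeros(20, int), 0, icd_floor=0.05)
        assert s.icd10_frequencies == {"I50": 1.0}  # Q24 at exactly 5% stays below the floor

    def test_missing_bmi_excluded_pairwise(self):
        meta = self.meta_from([50.0, 60.0, 70.0], bmis=[20.0, np.nan, 30.0])
        s = cluster_summary(meta, np.zeros(3, int), 0)
        assert s.bmi_median == 25.0
        assert s.age_median == 60.0

    def test_empty_cluster_rejected(self):
        meta = self.meta_from([50.0, 60.0])
        with pytest.raises(ValueError, match="empty"):
            cluster_summary(meta, np.zeros(2, int), 3)


class TestAssociationScore:
    def test_worked_examples(self):
        assert association_score({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert association_score({"a"}, {"a"}) == 1.0
        assert association_score({"a"}, {"b"}) == 0.0
        assert association_score(set(), set()) == 0.0

    @given(st.sets(st.integers(0, 15)), st.sets(st.integers(0, 15)))
    def test_symmetric_and_matches_brute_force(self, si, sj):
        score = association_score(si, sj)
        assert score == association_score(sj, si)
        inter = sum(1 for x in si if x in sj)
        union = len(si) + len(sj) - inter
        assert score == (inter / union if union else 0.0)


class TestAssociationAnalysis:
    @staticmethod
    def counts_from(arr):
        arr = np.asarray(arr)
        return PatientConceptMatrix(
            patient_index=tuple(f"P{i}" for i in range(arr.shape[0])),
            concept_index=tuple(f"C{j:07d}" for j in range(arr.shape[1])),
            counts=sp.csr_matrix(arr),
        )

    def test_planted_cooccurrence_within_exceeds_between(self):
        rng = np.random.default_rng(0)
        n = 60
        arr = np.zeros((n, 6), dtype=int)
        # concepts 0-2 co-occur in the first half, 3-5 in the second half
        arr[:30, :3] = rng.integers(1, 4, (30, 3))
        arr[30:, 3:] = rng.integers(1, 4, (30, 3))
        arr[rng.random((n, 6)) < 0.05] = 1  # sprinkle noise
        counts = self.counts_from(arr)
        report = association_analysis(
            counts,
            {0: ["C0000000", "C0000001", "C0000002"],
             1: ["C0000003", "C0000004", "C0000005"]},
        )
        assert report.mean_within > report.mean_between

    def test_ubiquitous_concepts_all_scores_one(self):
        counts = self.counts_from(np.ones((10, 4), dtype=int))
        report = association_analysis(
            counts, {0: ["C0000000", "C0000001"], 1: ["C0000002", "C0000003"]}
        )
        assert (report.pairs["score"] == 1.0).all()
        assert report.mean_within == report.mean_between

    def test_concept_in_two_clusters_pairs_are_within(self):
        counts = self.counts_from(np.eye(3, dtype=int))
        report = association_analysis(
            counts,
            {0: ["C0000000", "C0000001"], 1: ["C0000001", "C0000002"]},
        )
        kinds = {
            tuple(sorted((r.concept_i, r.concept_j))): r.pair_kind
            for r in report.pairs.itertuples()
        }
        # the shared concept C...1 is "within" with members of both clusters
        assert kinds[("C0000000", "C0000001")] == "within"
        assert kinds[("C0000001", "C0000002")] == "within"
        assert kinds[("C0000000", "C0000002")] == "between"

    def test_missing_concept_rejected(self):
        counts = self.counts_from(np.ones((4, 2), dtype=int))
        with pytest.raises(ValueError, match="missing"):
            association_analysis(counts, {0: ["C0000000", "C9999999"]})

    def test_no_self_pairs_and_symmetric_coverage(self):
        counts = self.counts_from(np.ones((5, 3), dtype=int))
        report = association_analysis(counts, {0: ["C0000000", "C0000001", "C0000002"]})
        assert len(report.pairs) == 3  # C(3,2)
        assert (report.pairs["concept_i"] != report.pairs["concept_j"]).all()
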