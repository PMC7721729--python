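"""Cluster characterization: concept enrichment, summaries, associations.

Each cluster is profiled three ways:

* **enrichment** — per concept, a one-sided (greater) two-sample t-test of
  its TF-IDF values inside the cluster against the rest of the cohort,
  Bonferroni-corrected over the whole comparison family (Welch by default);
* **descriptive summary** — demographics, BMI, in-hospital mortality and
  frequent ICD-10 codes of the cluster's patients;
* **concept association** — for the top significantly enriched concepts of
  every cluster at one K, the Jaccard co-occurrence score a_ij between each
  concept pair's cohort-wide patient presence sets, compared between pairs
  sharing a source cluster ("within") and pairs that do not ("between").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import PatientConceptMatrix
from .vectorize import TfidfMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_TOP_N = 10
DEFAULT_ICD_FLOOR = 0.05


def bonferroni_adjust(p_raw, m: int):
    """Family-wise adjusted p-value(s): min(1, m * p)."""
    if m < 1:
        raise ValueError(f"family size m must be >= 1, got {m}")
    p = np.asarray(p_raw, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.minimum(1.0, m * p)
    return float(adj) if np.isscalar(p_raw) else adj


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-concept overrepresentation tests for one cluster."""

    cluster_id: int
    table: pd.DataFrame = field(repr=False)  # concept_id, t, p_raw, p_adjusted, prevalences
    family_size: int

    def significant(self, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
        return self.table[self.table["p_adjusted"] <= alpha]


def enrich_cluster(
    X: TfidfMatrix,
    labels: np.ndarray,
    cluster_id: int,
    m: int,
    counts: PatientConceptMatrix | None = None,
    equal_var: bool = False,
) -> EnrichmentTable:
    """Test every concept for overrepresentation in one cluster.

    Welch (default) or pooled two-sample t-test per concept, alternative
    "cluster mean greater than the rest", corrected by Bonferroni with
    family size ``m``.  Prevalences (fraction of patients with a nonzero
    count) are taken from ``counts`` when given, else from the TF-IDF
    values.  Concepts with zero variance in both groups and equal means get
    p_raw = 1.0 by convention.
    """
    labels = np.asarray(labels)
    inside = labels == cluster_id
    n_in, n_out = int(inside.sum()), int((~inside).sum())
    if n_in < 2 or n_out < 2:
        raise ValueError(
            f"cluster {cluster_id} needs >= 2 members and >= 2 non-members "
            f"(got {n_in} / {n_out})"
        )
    a = X.values[inside]
    b = X.values[~inside]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var, alternative="greater")
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.info(
            "%d concept(s) with zero variance and equal means in cluster %d; p set to 1",
            int(degenerate.sum()), cluster_id,
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    src = counts.to_dense() if counts is not None else X.values
    if counts is not None and counts.concept_index != X.concept_index:
        raise ValueError("concept_index mismatch between counts and TF-IDF matrix")
    prev_in = (src[inside] > 0).mean(axis=0)
    prev_out = (src[~inside] > 0).mean(axis=0)
    table = pd.DataFrame(
        {
            "concept_id": X.concept_index,
            "t_statistic": t,
            "p_raw": p,
            "p_adjusted": bonferroni_adjust(p, m),
            "prevalence_in": prev_in,
            "prevalence_out": prev_out,
        }
    )
    return EnrichmentTable(cluster_id=cluster_id, table=table, family_size=m)


def top_concepts(
    table: EnrichmentTable, n: int = DEFAULT_TOP_N, alpha: float = DEFAULT_ALPHA
) -> list[str]:
    """Up to ``n`` significant concepts, most significant first.

    Sorted by raw p ascending; ties broken by larger t, then concept_id.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    sig = table.significant(alpha).sort_values(
        ["p_raw", "t_statistic", "concept_id"], ascending=[True, False, True]
    )
    return sig["concept_id"].head(n).tolist()


@dataclass(frozen=True)
class ClusterSummary:
    """Descriptive statistics of one cluster's patients."""

    cluster_id: int
    n_patients: int
    fraction_female: float
    age_median: float
    age_q25: float
    age_q75: float
    bmi_median: float
    bmi_q25: float
    bmi_q75: float
    in_hospital_mortality_fraction: float
    icd10_frequencies: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "n_patients": self.n_patients,
            "fraction_female": self.fraction_female,
            "age_years": {"median": self.age_median, "q25": self.age_q25, "q75": self.age_q75},
            "bmi": {"median": self.bmi_median, "q25": self.bmi_q25, "q75": self.bmi_q75},
            "in_hospital_mortality_fraction": self.in_hospital_mortality_fraction,
            "icd10_frequencies": self.icd10_frequencies,
        }


def cluster_summary(
    meta: pd.DataFrame,
    labels: np.ndarray,
    cluster_id: int,
    icd_floor: float = DEFAULT_ICD_FLOOR,
    female_label: str = "F",
) -> ClusterSummary:
    """Demographic/outcome profile of one cluster.

    Quartiles use the linear-interpolation percentile rule; missing age/BMI
    values are excluded per variable.  ICD-10 codes are reported with their
    within-cluster frequency when it exceeds ``icd_floor``.
    """
    labels = np.asarray(labels)
    members = meta.iloc[np.flatnonzero(labels == cluster_id)]
    if members.empty:
        raise ValueError(f"cluster {cluster_id} is empty")
    n = len(members)

    def _quartiles(series: pd.Series) -> tuple[float, float, float]:
        v = series.dropna().to_numpy(float)
        if v.size == 0:
            return (float("nan"),) * 3
        q25, med, q75 = np.percentile(v, [25, 50, 75], method="linear")
        return float(med), float(q25), float(q75)

    age_med, age_q25, age_q75 = _quartiles(members["age_years"])
    bmi_med, bmi_q25, bmi_q75 = _quartiles(members["bmi"])
    code_counts: dict[str, int] = {}
    for codes in members["icd10_codes"]:
        for c in codes:
            code_counts[c] = code_counts.get(c, 0) + 1
    icd = {
        c: cnt / n for c, cnt in sorted(code_counts.items()) if cnt / n > icd_floor
    }
    return ClusterSummary(
        cluster_id=cluster_id,
        n_patients=n,
        fraction_female=float((members["sex"] == female_label).mean()),
        age_median=age_med,
        age_q25=age_q25,
        age_q75=age_q75,
        bmi_median=bmi_med,
        bmi_q25=bmi_q25,
        bmi_q75=bmi_q75,
        in_hospital_mortality_fraction=float(members["died_in_hospital"].mean()),
        icd10_frequencies=icd,
    )


def association_score(presence_i: Iterable, presence_j: Iterable) -> float:
    """Jaccard co-occurrence a_ij = |P_i ∩ P_j| / |P_i ∪ P_j| between the
    patient sets in which two concepts appear; 0 when both are empty."""
    si, sj = set(presence_i), set(presence_j)
    union = si | sj
    if not union:
        logger.info("association_score of two empty presence sets; defined as 0")
        return 0.0
    return len(si & sj) / len(union)


@dataclass(frozen=True)
class AssociationReport:
    """Pairwise concept association scores with the within/between split."""

    pairs: pd.DataFrame = field(repr=False)
    mean_within: float
    mean_between: float
    comparison_p: float

    def to_summary_dict(self) -> dict:
        return {
            "n_pairs": int(len(self.pairs)),
            "n_within": int((self.pairs["pair_kind"] == "within").sum()),
            "n_between": int((self.pairs["pair_kind"] == "between").sum()),
            "mean_within": self.mean_within,
            "mean_between": self.mean_between,
            "comparison_p": self.comparison_p,
        }


def association_analysis(
    counts: PatientConceptMatrix,
    per_cluster_top: Mapping[int, Sequence[str]],
    presence: Mapping[str, frozenset] | None = None,
) -> AssociationReport:
    """Association scores among each cluster's top enriched concepts.

    Scores all unordered pairs of distinct concepts drawn from the union of
    the per-cluster top lists.  A pair is *within* when the two concepts
    share at least one source cluster, else *between*.  Presence sets are
    cohort-wide (count > 0) by default; an external document x concept
    presence table may be supplied instead via ``presence`` (concept ->
    document id set), enabling e.g. literature corpora.
    """
    sources: dict[str, set[int]] = {}
    for cid, concepts in per_cluster_top.items():
        for c in concepts:
            sources.setdefault(c, set()).add(cid)
    concept_list = sorted(sources)
    if presence is None:
        col = {c: j for j, c in enumerate(counts.concept_index)}
        missing = [c for c in concept_list if c not in col]
        if missing:
            raise ValueError(f"concepts missing from count matrix: {missing[:10]}")
        csc = counts.counts.tocsc()
        pid = np.asarray(counts.patient_index, dtype=object)
        presence = {
            c: frozenset(pid[csc[:, col[c]].nonzero()[0]]) for c in concept_list
        }
    else:
        missing = [c for c in concept_list if c not in presence]
        if missing:
            raise ValueError(f"concepts missing from presence table: {missing[:10]}")

    rows = []
    for ci, cj in combinations(concept_list, 2):
        shared = sorted(sources[ci] & sources[cj])
        rows.append(
            (
                ci,
                cj,
                ";".join(map(str, shared)),
                association_score(presence[ci], presence[cj]),
                "within" if shared else "between",
            )
        )
    pairs = pd.DataFrame(
        rows, columns=["concept_i", "concept_j", "cluster_context", "score", "pair_kind"]
    )
    within = pairs.loc[pairs["pair_kind"] == "within", "score"].to_numpy()
    between = pairs.loc[pairs["pair_kind"] == "between", "score"].to_numpy()
    mean_within = float(within.mean()) if within.size else float("nan")
    mean_between = float(between.mean()) if between.size else float("nan")
    if within.size >= 2 and between.size >= 2:
        if np.var(within) == 0 and np.var(between) == 0:
            comparison_p = 1.0 if mean_within <= mean_between else 0.0
            if mean_within == mean_between:
                comparison_p = 1.0
        else:
            comparison_p = float(
                stats.ttest_ind(within, between, equal_var=False, alternative="greater").pvalue
            )
    else:
        comparison_p = float("nan")
    return AssociationReport(
        pairs=pairs,
        mean_within=mean_within,
        mean_between=mean_between,
        comparison_p=comparison_p,
    )
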