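"""Synthetic EHR cohorts with planted hierarchical phenotype structure.

Real complaint-mention corpora of the kind this package analyses are rarely
shareable, so every pipeline stage is exercised against generated cohorts
with known ground truth.  The generative model:

* a rooted phenotype tree whose leaves are latent patient groups; each
  patient is drawn from a leaf by mixing weight;
* baseline concept usage follows a truncated power law (heavy-tailed
  concept popularity, default exponent 1.0 with per-concept mean counts
  capped at 5), scaled so an average patient mentions on the order of a
  hundred complaints — popular complaints are near-ubiquitous across
  patients yet average only a few mentions each, rather than one concept
  hoarding the mention mass;
* per-patient concept counts are negative-binomial (overdispersed — the
  same complaint is re-documented across encounters) with mean =
  baseline * multiplier, where signature concepts of the patient's leaf
  (and of its ancestors) carry multipliers > 1;
* counts are expanded into positively-asserted mention records; negated
  mentions and non-complaint "contaminant" mentions (medication-like
  semantic types) are injected at configurable rates so the complaint
  filter has real work to do;
* demographics, in-hospital mortality and ICD-10 codes are sampled per
  leaf.

Everything is deterministic given the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import (
    DEFAULT_COMPLAINT_TYPES,
    ConceptVocabulary,
    MentionRecord,
    validate_metadata,
)

_COMPLAINT_TYPE_CYCLE = (
    "Disease or Syndrome",
    "Sign or Symptom",
    "Finding",
    "Pathologic Function",
)
_CONTAMINANT_TYPES = ("Pharmacologic Substance", "Therapeutic or Preventive Procedure")


def concept_id(i: int) -> str:
    """CUI-like synthetic concept identifier."""
    return f"C{i:07d}"


@dataclass(frozen=True)
class LeafPhenotype:
    """One latent phenotype: signature enrichments plus a demographic profile."""

    name: str
    ancestry: tuple[str, ...]  # internal-node path from the root, root first
    signature: Mapping[str, float]  # concept_id -> mean multiplier (>= 1)
    mixing_weight: float
    age_mean: float = 60.0
    age_sd: float = 12.0
    p_female: float = 0.45
    bmi_mean: float = 27.0
    bmi_sd: float = 4.0
    p_mortality: float = 0.02
    icd_probs: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PhenotypeSpec:
    """A rooted phenotype tree given by its leaves' ancestry paths."""

    leaves: tuple[LeafPhenotype, ...]

    def __post_init__(self) -> None:
        if len(self.leaves) < 2:
            raise ValueError("need at least 2 leaf phenotypes")
        w = np.array([l.mixing_weight for l in self.leaves])
        if (w <= 0).any():
            raise ValueError("mixing weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixing weights must sum to 1 (got {w.sum():.6f})")
        for leaf in self.leaves:
            if any(m < 1 for m in leaf.signature.values()):
                raise ValueError(f"leaf {leaf.name}: multipliers must be >= 1")
        if len({l.name for l in self.leaves}) != len(self.leaves):
            raise ValueError("leaf names must be unique")

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.leaves)

    def supercluster_of(self, leaf_name: str) -> str:
        """First internal node below the root on the leaf's path (or the
        leaf itself for a flat tree)."""
        leaf = next(l for l in self.leaves if l.name == leaf_name)
        return leaf.ancestry[1] if len(leaf.ancestry) > 1 else leaf.name


@dataclass(frozen=True)
class CohortSpec:
    """Scale and noise parameters of a generated cohort."""

    n_patients: int = 3000
    n_concepts: int = 400
    power_exponent: float = 1.0
    max_baseline_mean: float = 5.0  # truncation of the per-concept mean count
    mean_mentions_per_patient: float = 120.0
    dispersion: float = 1.0  # negative-binomial size; smaller = more overdispersed
    negation_rate: float = 0.05
    contamination_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("negation_rate", "contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.n_concepts < 1 or self.mean_mentions_per_patient <= 0:
            raise ValueError("invalid cohort scale parameters")
        if self.dispersion <= 0 or self.power_exponent <= 0:
            raise ValueError("dispersion and power_exponent must be positive")
        if self.max_baseline_mean <= 0:
            raise ValueError("max_baseline_mean must be positive")

    def baseline_means(self) -> np.ndarray:
        """Per-concept baseline mean mention counts: power-law popularity,
        truncated so no single concept hoards the mention mass."""
        w = (np.arange(1, self.n_concepts + 1, dtype=float)) ** (-self.power_exponent)
        mu = self.mean_mentions_per_patient * w / w.sum()
        return np.minimum(mu, self.max_baseline_mean)

    def expected_unique_concepts(self) -> float:
        """Analytic expectation of unique concepts per baseline patient:
        sum_c P(count_c > 0) under the negative-binomial model."""
        mu = self.baseline_means()
        r = self.dispersion
        p_zero = (r / (r + mu)) ** r
        return float((1.0 - p_zero).sum())


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial draws with the given means and common size."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def default_vocabulary(cohort: CohortSpec, n_contaminants: int = 20) -> ConceptVocabulary:
    """Vocabulary covering the generated concepts plus contaminant entries."""
    entries: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(cohort.n_concepts):
        stype = _COMPLAINT_TYPE_CYCLE[i % len(_COMPLAINT_TYPE_CYCLE)]
        entries[concept_id(i)] = (f"concept_{i}", frozenset({stype}))
    for i in range(n_contaminants):
        cid = concept_id(9_000_000 + i)
        stype = _CONTAMINANT_TYPES[i % len(_CONTAMINANT_TYPES)]
        entries[cid] = (f"contaminant_{i}", frozenset({stype}))
    return ConceptVocabulary(entries=entries, whitelist=DEFAULT_COMPLAINT_TYPES)


def generate_cohort(
    pheno: PhenotypeSpec, cohort: CohortSpec
) -> tuple[list[MentionRecord], pd.DataFrame, pd.DataFrame]:
    """Draw a full synthetic cohort.

    Returns ``(mentions, metadata, truth)`` where truth records each
    patient's latent leaf and its ancestry path.  Mention records include
    injected negated and contaminant mentions; metadata covers every
    patient.  Byte-identical outputs for identical specs and seed.
    """
    rng = np.random.default_rng(cohort.seed)
    n, c = cohort.n_patients, cohort.n_concepts
    if n < len(pheno.leaves):
        raise ValueError("n_patients must be >= number of leaves")
    base_mu = cohort.baseline_means()

    weights = np.array([l.mixing_weight for l in pheno.leaves])
    leaf_idx = rng.choice(len(pheno.leaves), size=n, p=weights)

    # per-leaf mean profiles
    mult = np.ones((len(pheno.leaves), c))
    for li, leaf in enumerate(pheno.leaves):
        for cid, m in leaf.signature.items():
            j = int(cid[1:])
            if j >= c:
                raise ValueError(f"signature concept {cid} outside cohort vocabulary")
            mult[li, j] = m
    counts = _nb_sample(rng, base_mu[np.newaxis, :] * mult[leaf_idx], cohort.dispersion)

    patient_ids = [f"P{i:06d}" for i in range(n)]
    vocab = default_vocabulary(cohort)

    mentions: list[MentionRecord] = []
    rows, cols = counts.nonzero()
    for i, j in zip(rows, cols):
        cid = concept_id(j)
        name, types = vocab.entries[cid]
        rec = MentionRecord(
            patient_id=patient_ids[i],
            concept_id=cid,
            concept_name=name,
            semantic_types=tuple(sorted(types)),
            polarity="positive",
        )
        mentions.extend([rec] * int(counts[i, j]))
    n_pos = len(mentions)

    # negated mentions: concepts explicitly denied in the notes
    n_neg = int(round(cohort.negation_rate * n_pos))
    for i, j in zip(rng.integers(0, n, n_neg), rng.integers(0, c, n_neg)):
        cid = concept_id(int(j))
        name, types = vocab.entries[cid]
        mentions.append(
            MentionRecord(
                patient_id=patient_ids[int(i)],
                concept_id=cid,
                concept_name=name,
                semantic_types=tuple(sorted(types)),
                polarity="negative",
            )
        )

    # contaminants: non-complaint semantic types (interventions etc.)
    contaminant_ids = [cid for cid in vocab.entries if int(cid[1:]) >= 9_000_000]
    n_cont = int(round(cohort.contamination_rate * n_pos))
    for i, j in zip(rng.integers(0, n, n_cont), rng.integers(0, len(contaminant_ids), n_cont)):
        cid = contaminant_ids[int(j)]
        name, types = vocab.entries[cid]
        mentions.append(
            MentionRecord(
                patient_id=patient_ids[int(i)],
                concept_id=cid,
                concept_name=name,
                semantic_types=tuple(sorted(types)),
                polarity="positive",
            )
        )

    # demographics / outcomes per leaf
    age = np.empty(n)
    sex = np.empty(n, dtype=object)
    bmi = np.empty(n)
    died = np.empty(n, dtype=bool)
    icd: list[frozenset[str]] = [frozenset()] * n
    for li, leaf in enumerate(pheno.leaves):
        members = np.flatnonzero(leaf_idx == li)
        k = members.size
        if k == 0:
            continue
        age[members] = np.clip(rng.normal(leaf.age_mean, leaf.age_sd, k), 0.0, None)
        sex[members] = np.where(rng.random(k) < leaf.p_female, "F", "M")
        bmi[members] = np.clip(rng.normal(leaf.bmi_mean, leaf.bmi_sd, k), 12.0, None)
        died[members] = rng.random(k) < leaf.p_mortality
        codes = sorted(leaf.icd_probs)
        if codes:
            draws = rng.random((k, len(codes)))
            probs = np.array([leaf.icd_probs[cd] for cd in codes])
            for row, mi in enumerate(members):
                icd[mi] = frozenset(
                    cd for ci, cd in enumerate(codes) if draws[row, ci] < probs[ci]
                )
    meta = pd.DataFrame(
        {
            "age_years": np.round(age, 2),
            "sex": sex,
            "bmi": np.round(bmi, 2),
            "died_in_hospital": died,
            "icd10_codes": icd,
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    validate_metadata(meta)

    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "leaf": [pheno.leaves[li].name for li in leaf_idx],
            "ancestry": [
                "/".join((*pheno.leaves[li].ancestry, pheno.leaves[li].name))
                for li in leaf_idx
            ],
        }
    )
    return mentions, meta, truth


def generate_null_cohort(
    cohort: CohortSpec, profile: LeafPhenotype | None = None
) -> tuple[list[MentionRecord], pd.DataFrame, pd.DataFrame]:
    """Structureless cohort: one latent phenotype, all multipliers 1.

    Marginally identical to the baseline of :func:`generate_cohort`; used
    for type-I-error and stability-null checks.
    """
    base = profile or LeafPhenotype(
        name="null", ancestry=("root",), signature={}, mixing_weight=1.0
    )
    # PhenotypeSpec requires >= 2 leaves, so sample directly from one leaf.
    flat = PhenotypeSpec(
        leaves=(
            LeafPhenotype(
                name=base.name, ancestry=base.ancestry, signature={},
                mixing_weight=0.5, age_mean=base.age_mean, age_sd=base.age_sd,
                p_female=base.p_female, bmi_mean=base.bmi_mean, bmi_sd=base.bmi_sd,
                p_mortality=base.p_mortality, icd_probs=base.icd_probs,
            ),
            LeafPhenotype(
                name=base.name + "_b", ancestry=base.ancestry, signature={},
                mixing_weight=0.5, age_mean=base.age_mean, age_sd=base.age_sd,
                p_female=base.p_female, bmi_mean=base.bmi_mean, bmi_sd=base.bmi_sd,
                p_mortality=base.p_mortality, icd_probs=base.icd_probs,
            ),
        )
    )
    mentions, meta, truth = generate_cohort(flat, cohort)
    truth = truth.assign(leaf=base.name, ancestry="/".join((*base.ancestry, base.name)))
    return mentions, meta, truth


# ---------------------------------------------------------------------------
# Presets


def paper_scale_mini(
    multiplier: float = 12.0,
    n_signature: int = 10,
    seed: int = 0,
) -> tuple[PhenotypeSpec, CohortSpec]:
    """3,000 patients x 400 concepts, 6 leaves under 2 superclusters.

    Each supercluster carries ``n_signature`` shared signature concepts and
    each leaf ``n_signature`` private ones, all at the same enrichment
    multiplier; signature concepts occupy mid-popularity ranks so they are
    neither ubiquitous nor vanishingly rare.  Demographic profiles differ
    by leaf (one pediatric branch, one high-mortality leaf) so cluster
    summaries have visible contrasts.  Scaled for minutes-level runtimes.
    """
    cohort = CohortSpec(n_patients=3000, n_concepts=400, seed=seed)
    demo = [
        dict(age_mean=62, age_sd=9, p_female=0.25, bmi_mean=28, bmi_sd=4, p_mortality=0.01),
        dict(age_mean=64, age_sd=10, p_female=0.30, bmi_mean=28.5, bmi_sd=4, p_mortality=0.03),
        dict(age_mean=67, age_sd=9, p_female=0.40, bmi_mean=29, bmi_sd=4.5, p_mortality=0.005),
        dict(age_mean=63, age_sd=12, p_female=0.70, bmi_mean=30, bmi_sd=5, p_mortality=0.001),
        dict(age_mean=5, age_sd=4, p_female=0.50, bmi_mean=16, bmi_sd=2, p_mortality=0.06),
        dict(age_mean=55, age_sd=13, p_female=0.35, bmi_mean=27, bmi_sd=4, p_mortality=0.14),
    ]
    icd = [
        {"I50": 0.95, "I25": 0.6, "I20": 0.5},
        {"I50": 0.9, "I21": 0.7, "I25": 0.5},
        {"I50": 0.8, "I48": 0.7, "I10": 0.3},
        {"I11.0": 0.8, "I10": 0.9, "E66": 0.4},
        {"Q24": 0.9, "I50": 0.7},
        {"I42": 0.9, "I50": 0.6, "N18": 0.25},
    ]
    leaves = []
    for li in range(6):
        sc = li // 3  # supercluster index
        super_sig = {
            concept_id(20 + 10 * sc + j): multiplier for j in range(n_signature)
        }
        leaf_sig = {concept_id(40 + 10 * li + j): multiplier for j in range(n_signature)}
        leaves.append(
            LeafPhenotype(
                name=f"leaf{sc}_{li % 3}",
                ancestry=("root", f"super{sc}"),
                signature={**super_sig, **leaf_sig},
                mixing_weight=1.0 / 6.0,
                icd_probs=icd[li],
                **demo[li],
            )
        )
    return PhenotypeSpec(leaves=tuple(leaves)), cohort


def small_preset(seed: int = 0) -> tuple[PhenotypeSpec, CohortSpec]:
    """A 600-patient x 120-concept shrink of the mini preset (4 leaves under
    2 superclusters) for fast unit tests."""
    cohort = CohortSpec(
        n_patients=600, n_concepts=120, mean_mentions_per_patient=60.0, seed=seed
    )
    leaves = []
    for li in range(4):
        sc = li // 2
        sig = {concept_id(10 + 5 * sc + j): 12.0 for j in range(5)}
        sig.update({concept_id(20 + 5 * li + j): 12.0 for j in range(5)})
        leaves.append(
            LeafPhenotype(
                name=f"leaf{sc}_{li % 2}",
                ancestry=("root", f"super{sc}"),
                signature=sig,
                mixing_weight=0.25,
                icd_probs={"I50": 0.9},
            )
        )
    return PhenotypeSpec(leaves=tuple(leaves)), cohort


def leaf_signature_concepts(pheno: PhenotypeSpec, leaf_name: str, private_only: bool = True) -> set[str]:
    """Signature concept ids of one leaf; with ``private_only`` those not
    shared with any other leaf (i.e. excluding supercluster signatures)."""
    leaf = next(l for l in pheno.leaves if l.name == leaf_name)
    sig = set(leaf.signature)
    if private_only:
        for other in pheno.leaves:
            if other.name != leaf_name:
                sig -= set(other.signature)
    return sig
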