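"""Ingestion of clinical-concept mention records and aggregation into counts.

A *mention* is one occurrence of a normalized clinical concept (a CUI-like
identifier) in one patient's notes, carrying the concept's semantic type(s)
and an assertion polarity.  The phenotyping pipeline consumes only
positively-asserted *complaints* — concepts whose semantic type falls in a
configurable whitelist of disease/sign/symptom-like types — aggregated over
the patient's whole timeline into a patients x concepts count matrix.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
_POLARITIES = frozenset({POSITIVE, NEGATIVE})

#: Default semantic-type whitelist standing in for a site-specific list of
#: complaint-like UMLS semantic types.  Matching is case-insensitive.
DEFAULT_COMPLAINT_TYPES: frozenset[str] = frozenset(
    t.lower()
    for t in (
        "Disease or Syndrome",
        "Sign or Symptom",
        "Finding",
        "Pathologic Function",
        "Congenital Abnormality",
        "Mental or Behavioral Dysfunction",
        "Neoplastic Process",
        "Injury or Poisoning",
        "Anatomical Abnormality",
        "Cell or Molecular Dysfunction",
    )
)

_MENTION_FIELDS = ("patient_id", "concept_id", "concept_name", "semantic_type", "polarity")


@dataclass(frozen=True, slots=True)
class MentionRecord:
    """One concept mention in one patient's notes."""

    patient_id: str
    concept_id: str
    concept_name: str
    semantic_types: tuple[str, ...]
    polarity: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")
        if self.polarity not in _POLARITIES:
            raise ValueError(
                f"polarity must be one of {sorted(_POLARITIES)}, got {self.polarity!r}"
            )


@dataclass(frozen=True)
class ConceptVocabulary:
    """Concept id -> (name, semantic types) plus a complaint-type whitelist.

    Semantic-type tokens are matched case-insensitively; concept ids are
    case-sensitive codes.
    """

    entries: Mapping[str, tuple[str, frozenset[str]]]
    whitelist: frozenset[str]

    def __post_init__(self) -> None:
        if not self.whitelist:
            raise ValueError("whitelist must be non-empty")
        object.__setattr__(
            self, "whitelist", frozenset(t.lower() for t in self.whitelist)
        )
        used = {t.lower() for _, types in self.entries.values() for t in types}
        unused = self.whitelist - used
        if unused:
            logger.info("whitelisted semantic types unused by any entry: %s", sorted(unused))

    @property
    def unused_whitelist_types(self) -> frozenset[str]:
        used = {t.lower() for _, types in self.entries.values() for t in types}
        return self.whitelist - used

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.entries

    def is_complaint_type(self, semantic_types: Iterable[str]) -> bool:
        return any(t.lower() in self.whitelist for t in semantic_types)

    @classmethod
    def from_files(cls, vocab_path: str | Path, whitelist_path: str | Path) -> "ConceptVocabulary":
        """Read a vocabulary TSV (concept_id, concept_name, semantic_types
        pipe-delimited) and a plain-text whitelist (one type per line)."""
        entries: dict[str, tuple[str, frozenset[str]]] = {}
        with open(vocab_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{vocab_path}: line {lineno}: expected 3 tab-separated fields"
                    )
                cid, name, types = parts
                if cid in entries:
                    raise ValueError(f"{vocab_path}: line {lineno}: duplicate concept_id {cid!r}")
                entries[cid] = (name, frozenset(types.split("|")))
        with open(whitelist_path, encoding="utf-8") as fh:
            whitelist = frozenset(
                line.strip() for line in fh if line.strip() and not line.startswith("#")
            )
        return cls(entries=entries, whitelist=whitelist)

    def to_files(self, vocab_path: str | Path, whitelist_path: str | Path) -> None:
        with open(vocab_path, "w", encoding="utf-8") as fh:
            for cid in sorted(self.entries):
                name, types = self.entries[cid]
                fh.write(f"{cid}\t{name}\t{'|'.join(sorted(types))}\n")
        with open(whitelist_path, "w", encoding="utf-8") as fh:
            for t in sorted(self.whitelist):
                fh.write(t + "\n")


# ---------------------------------------------------------------------------
# Patient metadata


METADATA_COLUMNS = ("age_years", "sex", "bmi", "died_in_hospital", "icd10_codes")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a patient-metadata table (indexed by patient_id).

    Expected columns: age_years (non-negative), sex (categorical), bmi
    (positive or NaN), died_in_hospital (bool), icd10_codes (frozenset).
    """
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate patient_ids in metadata: {dupes[:5]}")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if (meta["age_years"] < 0).any():
        raise ValueError("age_years must be non-negative")
    bmi = meta["bmi"].dropna()
    if (bmi <= 0).any():
        raise ValueError("bmi must be positive where present")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the metadata TSV dialect (icd10_codes semicolon-delimited)."""
    meta = pd.read_csv(path, sep="\t", dtype={"patient_id": str}).set_index("patient_id")
    meta["died_in_hospital"] = meta["died_in_hospital"].astype(bool)
    meta["icd10_codes"] = [
        frozenset(str(c).split(";")) if pd.notna(c) and str(c) else frozenset()
        for c in meta["icd10_codes"]
    ]
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out["icd10_codes"] = [";".join(sorted(c)) for c in out["icd10_codes"]]
    out["died_in_hospital"] = out["died_in_hospital"].astype(int).astype(bool)
    out.to_csv(path, sep="\t", index_label="patient_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# Mention record I/O


def _parse_semantic_types(value) -> tuple[str, ...]:
    if isinstance(value, str):
        return tuple(value.split("|")) if "|" in value else (value,)
    if isinstance(value, (list, tuple)):
        return tuple(str(v) for v in value)
    raise ValueError(f"semantic_type must be a string or list, got {type(value).__name__}")


def read_mentions(path: str | Path, format: str = "jsonl") -> list[MentionRecord]:
    """Read mention records from JSONL or TSV, in file order, unfiltered.

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    if format not in ("jsonl", "tsv"):
        raise ValueError(f"unknown mention file format {format!r}; use 'jsonl' or 'tsv'")
    records: list[MentionRecord] = []
    with open(path, encoding="utf-8") as fh:
        if format == "jsonl":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
                records.append(_record_from_mapping(obj, path, lineno))
        else:
            header = fh.readline().rstrip("\n").split("\t")
            missing = [f for f in _MENTION_FIELDS if f not in header]
            if missing:
                raise ValueError(f"{path}: line 1: header missing columns {missing}")
            idx = {name: header.index(name) for name in _MENTION_FIELDS}
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(header):
                    raise ValueError(
                        f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
                    )
                obj = {name: parts[i] for name, i in idx.items()}
                records.append(_record_from_mapping(obj, path, lineno))
    return records


def _record_from_mapping(obj: Mapping, path, lineno: int) -> MentionRecord:
    missing = [f for f in _MENTION_FIELDS if f not in obj or obj[f] in (None, "")]
    if missing:
        raise ValueError(f"{path}: line {lineno}: missing field(s) {missing}")
    try:
        return MentionRecord(
            patient_id=str(obj["patient_id"]),
            concept_id=str(obj["concept_id"]),
            concept_name=str(obj["concept_name"]),
            semantic_types=_parse_semantic_types(obj["semantic_type"]),
            polarity=str(obj["polarity"]),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: line {lineno}: {exc}") from exc


def write_mentions(records: Sequence[MentionRecord], path: str | Path, format: str = "jsonl") -> None:
    if format not in ("jsonl", "tsv"):
        raise ValueError(f"unknown mention file format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        if format == "jsonl":
            for r in records:
                st = list(r.semantic_types) if len(r.semantic_types) > 1 else r.semantic_types[0]
                fh.write(
                    json.dumps(
                        {
                            "patient_id": r.patient_id,
                            "concept_id": r.concept_id,
                            "concept_name": r.concept_name,
                            "semantic_type": st,
                            "polarity": r.polarity,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
        else:
            fh.write("\t".join(_MENTION_FIELDS) + "\n")
            for r in records:
                fh.write(
                    "\t".join(
                        (
                            r.patient_id,
                            r.concept_id,
                            r.concept_name,
                            "|".join(r.semantic_types),
                            r.polarity,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Complaint filtering and aggregation


def filter_complaints(
    mentions: Sequence[MentionRecord],
    vocab: ConceptVocabulary,
    on_unknown: str = "warn",
) -> list[MentionRecord]:
    """Keep positively-asserted mentions with a whitelisted semantic type.

    Mentions whose concept_id is absent from the vocabulary are dropped with
    a warning (``on_unknown="warn"``, default) or raise (``"error"``).
    Relative order is preserved; the operation is idempotent.
    """
    if on_unknown not in ("warn", "error"):
        raise ValueError(f"on_unknown must be 'warn' or 'error', got {on_unknown!r}")
    kept: list[MentionRecord] = []
    unknown: set[str] = set()
    for r in mentions:
        if r.polarity != POSITIVE:
            continue
        if not vocab.is_complaint_type(r.semantic_types):
            continue
        if r.concept_id not in vocab:
            if on_unknown == "error":
                raise ValueError(f"concept_id {r.concept_id!r} absent from vocabulary")
            unknown.add(r.concept_id)
            continue
        kept.append(r)
    if unknown:
        warnings.warn(
            f"dropped mentions of {len(unknown)} concept id(s) absent from vocabulary",
            stacklevel=2,
        )
    return kept


@dataclass(frozen=True)
class PatientConceptMatrix:
    """Patients x concepts non-negative integer mention counts."""

    patient_index: tuple[str, ...]
    concept_index: tuple[str, ...]
    counts: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.patient_index)) != len(self.patient_index):
            raise ValueError("duplicate patient ids in patient_index")
        if len(set(self.concept_index)) != len(self.concept_index):
            raise ValueError("duplicate concept ids in concept_index")
        if self.counts.shape != (len(self.patient_index), len(self.concept_index)):
            raise ValueError("counts shape does not match indices")
        if (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def drop_zero_patients(self) -> tuple["PatientConceptMatrix", list[str]]:
        """Remove all-zero patients (no complaint representation); returns
        the reduced matrix and the excluded ids (logged)."""
        row_totals = np.asarray(self.counts.sum(axis=1)).ravel()
        keep = row_totals > 0
        excluded = [pid for pid, k in zip(self.patient_index, keep) if not k]
        if excluded:
            logger.info("excluding %d patients with zero complaint mentions", len(excluded))
        pcm = PatientConceptMatrix(
            patient_index=tuple(p for p, k in zip(self.patient_index, keep) if k),
            concept_index=self.concept_index,
            counts=self.counts[np.flatnonzero(keep)],
        )
        return pcm, excluded

    def save(self, prefix: str | Path) -> None:
        """Persist as MatrixMarket plus two one-id-per-line index files."""
        prefix = Path(prefix)
        mmwrite(str(prefix.with_suffix(".mtx")), self.counts.tocoo())
        prefix.with_suffix(".rows").write_text("\n".join(self.patient_index) + "\n")
        prefix.with_suffix(".cols").write_text("\n".join(self.concept_index) + "\n")

    @classmethod
    def load(cls, prefix: str | Path) -> "PatientConceptMatrix":
        prefix = Path(prefix)
        counts = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
        patients = tuple(prefix.with_suffix(".rows").read_text().splitlines())
        concepts = tuple(prefix.with_suffix(".cols").read_text().splitlines())
        return cls(patient_index=patients, concept_index=concepts, counts=counts)


def aggregate_counts(
    mentions: Sequence[MentionRecord], metadata: pd.DataFrame
) -> PatientConceptMatrix:
    """Aggregate complaint-filtered mentions into per-patient concept counts.

    Every metadata patient gets a row (all-zero if it has no mentions);
    concepts observed at least once form the columns, lexicographically
    sorted.  Mentions referencing patients absent from the metadata raise.
    """
    patient_index = tuple(str(p) for p in metadata.index)
    prow = {p: i for i, p in enumerate(patient_index)}
    unknown = sorted({m.patient_id for m in mentions if m.patient_id not in prow})
    if unknown:
        raise ValueError(f"mentions reference unknown patient_id(s): {unknown[:10]}")
    concept_index = tuple(sorted({m.concept_id for m in mentions}))
    ccol = {c: j for j, c in enumerate(concept_index)}
    rows = np.fromiter((prow[m.patient_id] for m in mentions), dtype=np.int64, count=len(mentions))
    cols = np.fromiter((ccol[m.concept_id] for m in mentions), dtype=np.int64, count=len(mentions))
    counts = sp.coo_matrix(
        (np.ones(len(mentions), dtype=np.int64), (rows, cols)),
        shape=(len(patient_index), len(concept_index)),
    ).tocsr()
    counts.sum_duplicates()
    return PatientConceptMatrix(patient_index=patient_index, concept_index=concept_index, counts=counts)
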