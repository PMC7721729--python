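"""TF-IDF representation of patient complaint-count profiles.

Each patient's record is treated as a document over the complaint
vocabulary: the term frequency is the raw mention count aggregated over the
patient's whole timeline, and the inverse document frequency penalizes
complaints mentioned for many patients in the cohort.  Defaults follow the
standard smoothed convention

    idf(c) = ln((1 + N) / (1 + df_c)) + 1

with L2 row normalization, which places patients on the unit sphere so that
Euclidean K-means distance is monotone in cosine similarity.  All three
choices (tf, idf, norm) are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import PatientConceptMatrix

TF_VARIANTS = ("raw", "log1p")
IDF_VARIANTS = ("smooth", "plain")
NORM_VARIANTS = ("l2", "none")


@dataclass(frozen=True)
class IdfVector:
    concept_index: tuple[str, ...]
    idf: np.ndarray = field(repr=False)
    df: np.ndarray = field(repr=False)
    n_docs: int

    def __post_init__(self) -> None:
        if len(self.idf) != len(self.concept_index):
            raise ValueError("idf length does not match concept_index")
        if not np.all(np.isfinite(self.idf)) or np.any(self.idf <= 0):
            raise ValueError("idf values must be finite and positive")

    def save(self, path: str | Path) -> None:
        pd.DataFrame(
            {"concept_id": self.concept_index, "df": self.df, "idf": self.idf}
        ).to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def load(cls, path: str | Path, n_docs: int) -> "IdfVector":
        t = pd.read_csv(path, sep="\t")
        return cls(
            concept_index=tuple(t["concept_id"]),
            idf=t["idf"].to_numpy(float),
            df=t["df"].to_numpy(int),
            n_docs=n_docs,
        )


@dataclass(frozen=True)
class TfidfMatrix:
    patient_index: tuple[str, ...]
    concept_index: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    normalized: bool

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.patient_index), len(self.concept_index)):
            raise ValueError("values shape does not match indices")
        if (self.values < 0).any():
            raise ValueError("TF-IDF values must be non-negative")
        if self.normalized:
            norms = np.linalg.norm(self.values, axis=1)
            nz = norms > 0
            if nz.any() and not np.allclose(norms[nz], 1.0, atol=1e-9):
                raise ValueError("normalized=True but some nonzero rows are not unit norm")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def compute_idf(counts: PatientConceptMatrix, variant: str = "smooth") -> IdfVector:
    """Inverse document frequencies from a count matrix.

    ``smooth`` (default): ln((1+N)/(1+df)) + 1; ``plain``: ln(N/df) + 1.
    Every concept must appear in at least one patient (zero-df concepts
    should have been dropped during aggregation).
    """
    if variant not in IDF_VARIANTS:
        raise ValueError(f"idf variant must be one of {IDF_VARIANTS}, got {variant!r}")
    n = len(counts.patient_index)
    df = np.asarray((counts.counts > 0).sum(axis=0)).ravel().astype(np.int64)
    if (df == 0).any():
        bad = [c for c, d in zip(counts.concept_index, df) if d == 0]
        raise ValueError(f"concepts with zero document frequency: {bad[:10]}")
    if variant == "smooth":
        idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    else:
        idf = np.log(n / df) + 1.0
    return IdfVector(concept_index=counts.concept_index, idf=idf, df=df, n_docs=n)


def tfidf_transform(
    counts: PatientConceptMatrix,
    idf: IdfVector | None = None,
    tf: str = "raw",
    norm: str = "l2",
    idf_variant: str = "smooth",
) -> TfidfMatrix:
    """TF-IDF weight each patient's count vector.

    value(p, c) = tf(count(p, c)) * idf(c), with optional L2 row
    normalization (all-zero rows are left as zero).  ``idf`` defaults to
    :func:`compute_idf` on the same matrix.
    """
    if tf not in TF_VARIANTS:
        raise ValueError(f"tf variant must be one of {TF_VARIANTS}, got {tf!r}")
    if norm not in NORM_VARIANTS:
        raise ValueError(f"norm must be one of {NORM_VARIANTS}, got {norm!r}")
    if idf is None:
        idf = compute_idf(counts, variant=idf_variant)
    if idf.concept_index != counts.concept_index:
        raise ValueError("concept_index mismatch between counts and idf")
    c = counts.to_dense().astype(np.float64)
    tfv = np.log1p(c) if tf == "log1p" else c
    values = tfv * idf.idf[np.newaxis, :]
    if norm == "l2":
        norms = np.linalg.norm(values, axis=1, keepdims=True)
        np.divide(values, norms, out=values, where=norms > 0)
    return TfidfMatrix(
        patient_index=counts.patient_index,
        concept_index=counts.concept_index,
        values=values,
        normalized=(norm == "l2"),
    )
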