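"""Staged pipeline orchestration.

``run_pipeline`` executes ingest → vectorize → cluster → stability →
hierarchy → characterize → associate from a single :class:`RunConfig`
(optionally preceded by a synthetic-cohort simulate stage), writing each
stage's outputs under ``out_dir/<stage>/`` so that any downstream stage can
be re-run from disk without recomputation.  A manifest with the full
configuration echo and SHA-256 hashes of every output file makes rerun
identity checkable; all randomness derives from the single master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
import scipy.sparse as sp

from . import characterize, clustering, corpus, hierarchy, synthetic, vectorize
from .corpus import ConceptVocabulary, PatientConceptMatrix
from .vectorize import TfidfMatrix

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of (``preset``/synthetic generation) and (real input paths
    ``mentions``/``metadata``/``vocabulary``/``whitelist``) must be set.
    """

    out_dir: str
    # synthetic input
    preset: str | None = None  # "paper-mini" | "small"
    # real input
    mentions: str | None = None
    mentions_format: str = "jsonl"
    metadata: str | None = None
    vocabulary: str | None = None
    whitelist: str | None = None
    # tf-idf
    tf: str = "raw"
    idf: str = "smooth"
    norm: str = "l2"
    min_df: int = 1
    # clustering / stability
    k_min: int = 2
    k_max: int = 10
    n_init: int = clustering.DEFAULT_N_INIT
    n_bootstrap: int = clustering.DEFAULT_N_BOOTSTRAP
    bootstrap_n_init: int = clustering.DEFAULT_BOOTSTRAP_N_INIT
    stability_threshold: float = clustering.DEFAULT_STABILITY_THRESHOLD
    # characterization
    alpha: float = characterize.DEFAULT_ALPHA
    top_n: int = characterize.DEFAULT_TOP_N
    # master seed
    seed: int = 0

    def __post_init__(self) -> None:
        real = all(p is not None for p in (self.mentions, self.metadata, self.vocabulary, self.whitelist))
        some_real = any(p is not None for p in (self.mentions, self.metadata, self.vocabulary, self.whitelist))
        if self.preset is not None and some_real:
            raise ValueError("config must set either a synthetic preset or real input paths, not both")
        if self.preset is None and not real:
            raise ValueError("config must set a synthetic preset or all four real input paths")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")

    @property
    def k_values(self) -> list[int]:
        return list(range(self.k_min, self.k_max + 1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    d = Path(cfg.out_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: RunConfig) -> Path:
    """Generate a synthetic cohort and write it in the ingestion dialects."""
    if cfg.preset is None:
        raise ValueError("simulate stage requires a synthetic preset")
    if cfg.preset == "paper-mini":
        pheno, cohort = synthetic.paper_scale_mini(seed=cfg.seed)
    elif cfg.preset == "small":
        pheno, cohort = synthetic.small_preset(seed=cfg.seed)
    else:
        raise ValueError(f"unknown preset {cfg.preset!r}")
    mentions, meta, truth = synthetic.generate_cohort(pheno, cohort)
    vocab = synthetic.default_vocabulary(cohort)
    out = _stage_dir(cfg, "simulate")
    corpus.write_mentions(mentions, out / "mentions.jsonl", format="jsonl")
    corpus.write_metadata(meta, out / "metadata.tsv")
    vocab.to_files(out / "vocabulary.tsv", out / "whitelist.txt")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    logger.info("simulate: %d mentions, %d patients", len(mentions), len(meta))
    return out


def _input_paths(cfg: RunConfig) -> tuple[Path, str, Path, Path, Path]:
    if cfg.preset is not None:
        sim = Path(cfg.out_dir) / "simulate"
        return (sim / "mentions.jsonl", "jsonl", sim / "metadata.tsv",
                sim / "vocabulary.tsv", sim / "whitelist.txt")
    return (Path(cfg.mentions), cfg.mentions_format, Path(cfg.metadata),
            Path(cfg.vocabulary), Path(cfg.whitelist))


def stage_ingest(cfg: RunConfig) -> PatientConceptMatrix:
    """Read, complaint-filter and aggregate mention records into counts."""
    mpath, fmt, metapath, vpath, wpath = _input_paths(cfg)
    mentions = corpus.read_mentions(mpath, format=fmt)
    vocab = ConceptVocabulary.from_files(vpath, wpath)
    meta = corpus.read_metadata(metapath)
    complaints = corpus.filter_complaints(mentions, vocab)
    logger.info("ingest: %d/%d mentions kept by complaint filter", len(complaints), len(mentions))
    counts = corpus.aggregate_counts(complaints, meta)
    if cfg.min_df > 1:
        df = np.asarray((counts.counts > 0).sum(axis=0)).ravel()
        keep = np.flatnonzero(df >= cfg.min_df)
        counts = PatientConceptMatrix(
            patient_index=counts.patient_index,
            concept_index=tuple(counts.concept_index[j] for j in keep),
            counts=counts.counts[:, keep].tocsr(),
        )
    out = _stage_dir(cfg, "ingest")
    counts.save(out / "counts")
    return counts


def _load_counts(cfg: RunConfig) -> PatientConceptMatrix:
    return PatientConceptMatrix.load(Path(cfg.out_dir) / "ingest" / "counts")


def stage_vectorize(cfg: RunConfig) -> TfidfMatrix:
    counts, _ = _load_counts(cfg).drop_zero_patients()
    idf = vectorize.compute_idf(counts, variant=cfg.idf)
    X = vectorize.tfidf_transform(counts, idf, tf=cfg.tf, norm=cfg.norm)
    out = _stage_dir(cfg, "vectorize")
    idf.save(out / "idf.tsv")
    mmwrite(str(out / "tfidf.mtx"), sp.coo_matrix(X.values))
    (out / "tfidf.rows").write_text("\n".join(X.patient_index) + "\n")
    (out / "tfidf.cols").write_text("\n".join(X.concept_index) + "\n")
    return X


def _load_tfidf(cfg: RunConfig) -> TfidfMatrix:
    out = Path(cfg.out_dir) / "vectorize"
    values = np.asarray(sp.csr_matrix(mmread(str(out / "tfidf.mtx"))).todense())
    patients = tuple((out / "tfidf.rows").read_text().splitlines())
    concepts = tuple((out / "tfidf.cols").read_text().splitlines())
    # persisted values are rounded; re-normalize when the run uses L2 rows
    normalized = cfg.norm == "l2"
    if normalized:
        norms = np.linalg.norm(values, axis=1, keepdims=True)
        np.divide(values, norms, out=values, where=norms > 0)
    return TfidfMatrix(
        patient_index=patients, concept_index=concepts, values=values, normalized=normalized
    )


def stage_cluster(cfg: RunConfig) -> dict[int, clustering.ClusteringResult]:
    X = _load_tfidf(cfg)
    results = clustering.sweep_kmeans(X, cfg.k_values, cfg.seed, n_init=cfg.n_init)
    out = _stage_dir(cfg, "cluster")
    clustering.labels_frame(results, X.patient_index).to_csv(
        out / "labels.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"K": list(results), "inertia": [results[K].inertia for K in results],
         "seed": [results[K].seed for K in results]}
    ).to_csv(out / "inertia.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return results


def _load_clusterings(cfg: RunConfig, X: TfidfMatrix) -> dict[int, clustering.ClusteringResult]:
    labels, patients = clustering.load_labels(Path(cfg.out_dir) / "cluster" / "labels.tsv")
    if list(patients) != list(X.patient_index):
        raise ValueError("patient order in labels.tsv does not match the TF-IDF matrix")
    return {K: clustering.result_from_labels(X, lab, seed=-1) for K, lab in labels.items()}


def stage_stability(cfg: RunConfig) -> list[clustering.StabilityReport]:
    X = _load_tfidf(cfg)
    results = _load_clusterings(cfg, X)
    reports = [
        clustering.bootstrap_stability(
            X, results[K], B=cfg.n_bootstrap,
            seed=clustering.derive_seed(cfg.seed, 7, K),
            threshold=cfg.stability_threshold, n_init=cfg.bootstrap_n_init,
        )
        for K in sorted(results)
    ]
    out = _stage_dir(cfg, "stability")
    clustering.stability_frame(reports).to_csv(
        out / "stability.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    return reports


def _load_stable_k(cfg: RunConfig) -> list[int]:
    t = pd.read_csv(Path(cfg.out_dir) / "stability" / "stability.tsv", sep="\t")
    return sorted(t.loc[t["stable_K"], "K"].unique().astype(int))


def stage_hierarchy(cfg: RunConfig) -> hierarchy.PhenotypeDendrogram | None:
    X = _load_tfidf(cfg)
    results = _load_clusterings(cfg, X)
    stable = _load_stable_k(cfg)
    out = _stage_dir(cfg, "hierarchy")
    if not stable:
        logger.warning("hierarchy: no stable K; writing empty outputs")
        (out / "dendrogram.nwk").write_text(";\n")
        (out / "edges.tsv").write_text(
            "child_K\tchild_id\tparent_K\tparent_id\tjaccard\tdissimilarity\n"
        )
        return None
    tree = hierarchy.build_dendrogram({K: results[K] for K in stable}, X.patient_index)
    (out / "dendrogram.nwk").write_text(hierarchy.to_newick(tree) + "\n")
    tree.edge_table().to_csv(out / "edges.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return tree


def stage_characterize(cfg: RunConfig) -> None:
    """Enrichment tables and descriptive summaries for every stable K."""
    X = _load_tfidf(cfg)
    counts, _ = _load_counts(cfg).drop_zero_patients()
    results = _load_clusterings(cfg, X)
    _, _, metapath, vpath, _ = _input_paths(cfg)
    meta = corpus.read_metadata(metapath).loc[list(X.patient_index)]
    vocab_names = {
        cid: name for cid, (name, _) in ConceptVocabulary.from_files(
            vpath, _input_paths(cfg)[4]
        ).entries.items()
    }
    out = _stage_dir(cfg, "characterize")
    for K in _load_stable_k(cfg):
        kdir = out / f"K{K}"
        kdir.mkdir(exist_ok=True)
        m = len(X.concept_index) * K
        summaries = []
        for cid in range(K):
            table = characterize.enrich_cluster(
                X, results[K].labels, cid, m, counts=counts
            )
            t = table.table.copy()
            t.insert(1, "concept_name", [vocab_names.get(c, "") for c in t["concept_id"]])
            t.to_csv(
                kdir / f"cluster{cid}_enrichment.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT,
            )
            summaries.append(
                characterize.cluster_summary(meta, results[K].labels, cid).to_dict()
            )
        (kdir / "summaries.json").write_text(
            json.dumps(summaries, indent=2, sort_keys=True) + "\n"
        )


def stage_associate(cfg: RunConfig) -> None:
    """Association analysis over each stable K's top enriched concepts,
    reading the characterize stage's tables from disk."""
    counts, _ = _load_counts(cfg).drop_zero_patients()
    char_dir = Path(cfg.out_dir) / "characterize"
    out = _stage_dir(cfg, "associate")
    for K in _load_stable_k(cfg):
        per_cluster_top: dict[int, list[str]] = {}
        for cid in range(K):
            t = pd.read_csv(char_dir / f"K{K}" / f"cluster{cid}_enrichment.tsv", sep="\t")
            table = characterize.EnrichmentTable(
                cluster_id=cid, table=t, family_size=len(t) * K
            )
            per_cluster_top[cid] = characterize.top_concepts(
                table, n=cfg.top_n, alpha=cfg.alpha
            )
        report = characterize.association_analysis(counts, per_cluster_top)
        report.pairs.to_csv(
            out / f"K{K}_pairs.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        (out / f"K{K}_summary.json").write_text(
            json.dumps(report.to_summary_dict(), indent=2, sort_keys=True) + "\n"
        )


# ---------------------------------------------------------------------------
# Orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    hashes = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {"config": cfg.to_dict(), "files": hashes}
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages in order; returns the manifest path."""
    stages = []
    if cfg.preset is not None:
        stages.append(("simulate", stage_simulate))
    stages += [
        ("ingest", stage_ingest),
        ("vectorize", stage_vectorize),
        ("cluster", stage_cluster),
        ("stability", stage_stability),
        ("hierarchy", stage_hierarchy),
        ("characterize", stage_characterize),
        ("associate", stage_associate),
    ]
    for name, fn in stages:
        try:
            logger.info("stage %s: starting", name)
            fn(cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return write_manifest(cfg)
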