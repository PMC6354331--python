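"""Synthetic literature corpora with planted disease clusters.

Diseases are grouped into clusters, each cluster owning a pool of signature
genes (optionally sharing a fraction with the next cluster on a ring). Every
abstract of a disease draws genes from its cluster pool with probability
``pool_gene_prob`` and from a common background pool otherwise, so planted
genes are over-represented in their diseases' literature and the pipeline can
be exercised end to end with known ground truth.

Synthetic disease ids use the reserved ``D9xxxxx`` shape and gene ids are
plain integers, so fixtures can never be confused with real vocabulary data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus_io import (
    AnnotationCorpus,
    DiseasePubmedRecord,
    GenePubmedRecord,
    HUMAN_TAX_ID,
    MeshTreeEntry,
    build_corpus,
    write_disease2pubmed,
    write_gene2pubmed,
    write_mesh_tree,
)
from .evaluation import ExpertLabels, NON_RELATED, RELATED, UNDEFINED, write_labels

#: Synthetic tree branch; all generated diseases live under it.
SYNTHETIC_BRANCH = "C99"

_POOL_GENE_BASE = 1_000
_BACKGROUND_GENE_BASE = 500_000
_PMID_BASE = 10_000_000


@dataclass
class SyntheticSpec:
    n_clusters: int = 3
    diseases_per_cluster: int = 6
    pool_genes_per_cluster: int = 40
    background_genes: int = 200
    pmids_per_disease: tuple[int, int] = (30, 60)
    genes_per_pmid: tuple[int, int] = (3, 8)
    pool_gene_prob: float = 0.8
    cross_pool_overlap: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pool_gene_prob <= 1.0:
            raise ValueError("pool_gene_prob must be in (0, 1]")
        if not 0.0 <= self.cross_pool_overlap < 1.0:
            raise ValueError("cross_pool_overlap must be in [0, 1)")
        for name in (
            "n_clusters",
            "diseases_per_cluster",
            "pool_genes_per_cluster",
            "background_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pmids_per_disease", "genes_per_pmid"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be a positive (low, high) range")
        if self.genes_per_pmid[1] > self.pool_genes_per_cluster:
            raise ValueError(
                "infeasible spec: genes_per_pmid max exceeds the cluster pool size"
            )
        if self.genes_per_pmid[1] > self.background_genes:
            raise ValueError(
                "infeasible spec: genes_per_pmid max exceeds the background pool"
            )


@dataclass
class SyntheticTruth:
    cluster_of: dict[str, int]
    planted_genes: dict[str, set[int]]
    labels: ExpertLabels | None = None


def _cluster_pools(spec: SyntheticSpec) -> list[np.ndarray]:
    """Gene pools per cluster; adjacent clusters on a ring share a fraction."""
    shared = int(round(spec.cross_pool_overlap * spec.pool_genes_per_cluster))
    own = spec.pool_genes_per_cluster - shared
    unique = [
        np.arange(
            _POOL_GENE_BASE + c * spec.pool_genes_per_cluster,
            _POOL_GENE_BASE + c * spec.pool_genes_per_cluster + spec.pool_genes_per_cluster,
        )
        for c in range(spec.n_clusters)
    ]
    if shared == 0 or spec.n_clusters < 2:
        return unique
    pools = []
    for c in range(spec.n_clusters):
        borrowed = unique[(c + 1) % spec.n_clusters][:shared]
        pools.append(np.concatenate([unique[c][:own], borrowed]))
    return pools


def disease_id_for(index: int) -> str:
    return f"D9{index:05d}"


def generate(spec: SyntheticSpec) -> tuple[AnnotationCorpus, SyntheticTruth]:
    """Draw a corpus from the spec; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    pools = _cluster_pools(spec)
    background = np.arange(
        _BACKGROUND_GENE_BASE, _BACKGROUND_GENE_BASE + spec.background_genes
    )

    gene_records: list[GenePubmedRecord] = []
    disease_records: list[DiseasePubmedRecord] = []
    cluster_of: dict[str, int] = {}
    planted: dict[str, set[int]] = {}

    pmid = _PMID_BASE
    index = 0
    for cluster in range(spec.n_clusters):
        pool = pools[cluster]
        for _ in range(spec.diseases_per_cluster):
            disease_id = disease_id_for(index)
            index += 1
            cluster_of[disease_id] = cluster
            planted[disease_id] = set(int(g) for g in pool)
            n_pmids = int(
                rng.integers(spec.pmids_per_disease[0], spec.pmids_per_disease[1] + 1)
            )
            for _ in range(n_pmids):
                pmid += 1
                disease_records.append(DiseasePubmedRecord(pmid, disease_id))
                n_genes = int(
                    rng.integers(spec.genes_per_pmid[0], spec.genes_per_pmid[1] + 1)
                )
                n_pool = int(rng.binomial(n_genes, spec.pool_gene_prob))
                chosen: list[int] = []
                if n_pool:
                    chosen.extend(
                        int(g) for g in rng.choice(pool, size=n_pool, replace=False)
                    )
                if n_genes - n_pool:
                    chosen.extend(
                        int(g)
                        for g in rng.choice(
                            background, size=n_genes - n_pool, replace=False
                        )
                    )
                for gene in chosen:
                    gene_records.append(GenePubmedRecord(HUMAN_TAX_ID, gene, pmid))

    universe = sorted(cluster_of)
    corpus = build_corpus(gene_records, disease_records, universe)
    return corpus, SyntheticTruth(cluster_of=cluster_of, planted_genes=planted)


def make_labels(
    truth: SyntheticTruth,
    query_id: str,
    undefined_fraction: float = 0.0,
    seed: int = 0,
) -> ExpertLabels:
    """Labels derived from planted clusters: related iff same cluster as the
    query; a seeded random ``undefined_fraction`` of non-query diseases is
    relabeled undefined."""
    if query_id not in truth.cluster_of:
        raise ValueError(f"query {query_id} not among synthetic diseases")
    if not 0.0 <= undefined_fraction <= 1.0:
        raise ValueError("undefined_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    others = sorted(d for d in truth.cluster_of if d != query_id)
    query_cluster = truth.cluster_of[query_id]
    labels = {
        d: RELATED if truth.cluster_of[d] == query_cluster else NON_RELATED
        for d in others
    }
    n_undefined = int(round(undefined_fraction * len(others)))
    for d in rng.choice(others, size=n_undefined, replace=False):
        labels[str(d)] = UNDEFINED
    return ExpertLabels(query_id=query_id, labels=labels)


def mesh_tree_entries(truth: SyntheticTruth) -> list[MeshTreeEntry]:
    """Synthetic vocabulary entries placing every disease under C99.<cluster>."""
    entries = []
    for i, disease_id in enumerate(sorted(truth.cluster_of)):
        cluster = truth.cluster_of[disease_id]
        entries.append(
            MeshTreeEntry(
                disease_id=disease_id,
                name=f"synthetic disease {disease_id}",
                tree_numbers=(f"{SYNTHETIC_BRANCH}.{cluster}.{i}",),
            )
        )
    return entries


def write_synthetic(
    corpus: AnnotationCorpus,
    truth: SyntheticTruth,
    out_dir: str | Path,
    labels: ExpertLabels | None = None,
) -> dict[str, Path]:
    """Write the corpus as exchange files (plus truth.json and labels.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene2pubmed": out / "gene2pubmed.tsv",
        "disease2pubmed": out / "disease2pubmed.tsv",
        "mesh_tree": out / "mesh_tree.tsv",
        "truth": out / "truth.json",
    }
    write_gene2pubmed(corpus.pmid_to_genes, paths["gene2pubmed"])
    write_disease2pubmed(corpus.pmid_to_diseases, paths["disease2pubmed"])
    write_mesh_tree(mesh_tree_entries(truth), paths["mesh_tree"])
    payload = {
        "cluster_of": truth.cluster_of,
        "planted_genes": {d: sorted(g) for d, g in truth.planted_genes.items()},
    }
    paths["truth"].write_text(
        json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
    )
    if labels is not None:
        paths["labels"] = out / "labels.tsv"
        write_labels(labels, paths["labels"])
    return paths
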