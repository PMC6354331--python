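"""Disease-disease distances, spectral clustering and related-disease calls.

The pipeline composes: fingerprints -> filtered disease x gene matrix ->
low-rank reconstruction -> Spearman correlation distance -> spectral
clustering -> same-cluster relatedness calls for a query disease.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from . import lowrank
from .corpus_io import AnnotationCorpus
from .fingerprint import build_fingerprint
from .matrix_builder import DiseaseGeneMatrix, build_matrix

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Square symmetric disease-disease distance matrix, entries in [0, 2]."""

    ids: list[str]
    values: np.ndarray


@dataclass
class ClusterAssignment:
    ids: list[str]
    labels: np.ndarray
    k: int
    seed: int

    def members(self, label: int) -> set[str]:
        return {d for d, l in zip(self.ids, self.labels) if l == label}

    def label_of(self, disease_id: str) -> int:
        return int(self.labels[self.ids.index(disease_id)])


@dataclass
class AssociationResult:
    query_id: str
    related: set[str]
    parameters: dict


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline; one seed drives all randomness."""

    min_genes: int = 1
    p_tail: str = "upper"
    log_base: float = 10.0
    p_cutoff: float | None = None
    energy_target: float = 0.95
    energy_mode: str = "sum"
    rank: int | None = None
    k: int = 2
    seed: int = 0
    count_after_gene_filter: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def spearman_distance(
    matrix: DiseaseGeneMatrix | np.ndarray, ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise 1 - Spearman correlation of the rows; ties get average ranks.

    Rows must be non-constant (a constant row has undefined rank correlation);
    the error names the offending disease.
    """
    if isinstance(matrix, DiseaseGeneMatrix):
        a, row_ids = matrix.values, list(matrix.row_ids)
    else:
        a = np.asarray(matrix, dtype=float)
        row_ids = list(ids) if ids is not None else [str(i) for i in range(len(a))]
    if a.shape[0] < 3:
        raise ValueError(f"need >= 3 rows for a distance matrix, got {a.shape[0]}")
    spans = a.max(axis=1) - a.min(axis=1)
    constant = np.nonzero(spans == 0)[0]
    if constant.size:
        raise ValueError(
            f"constant row(s) have undefined rank correlation: "
            f"{[row_ids[i] for i in constant]}"
        )
    ranks = rankdata(a, axis=1)
    rho = np.corrcoef(ranks)
    d = 1.0 - rho
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=row_ids, values=d)


def spectral_cluster(
    dist: DistanceMatrix, k: int, seed: int, n_restarts: int = 50
) -> ClusterAssignment:
    """Normalized-Laplacian spectral clustering of a distance matrix.

    Affinity is a Gaussian kernel ``exp(-d^2 / (2 sigma^2))`` with sigma set
    to the median off-diagonal distance. The top-k eigenvectors of
    ``D^{-1/2} A D^{-1/2}`` are row-normalized and clustered with seeded
    k-means (``n_restarts`` initialisations, best inertia wins). Labels are
    renumbered by order of first appearance, so the assignment is
    deterministic given (dist, k, seed).
    """
    n = len(dist.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        return ClusterAssignment(list(dist.ids), np.zeros(n, dtype=int), 1, seed)

    d = dist.values
    off_diag = d[~np.eye(n, dtype=bool)]
    sigma = float(np.median(off_diag))
    if sigma <= 0:
        log.warning("degenerate distance matrix (median off-diagonal 0)")
        sigma = 1.0
    affinity = np.exp(-(d**2) / (2.0 * sigma**2))
    np.fill_diagonal(affinity, 0.0)

    n_components, _ = connected_components(affinity > 1e-12, directed=False)
    if n_components > 1:
        log.warning(
            "affinity graph has %d connected components; clustering proceeds "
            "per component through the embedding",
            n_components,
        )

    degrees = affinity.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(degrees > 0, 1.0 / np.sqrt(degrees), 0.0)
    sym = affinity * inv_sqrt[:, None] * inv_sqrt[None, :]
    eigvals, eigvecs = eigh(sym)
    embedding = eigvecs[:, -k:]  # k largest eigenvalues
    norms = np.linalg.norm(embedding, axis=1, keepdims=True)
    embedding = np.where(norms > 0, embedding / np.where(norms == 0, 1, norms), 0.0)

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(embedding)
    labels = _canonical_labels(raw)
    return ClusterAssignment(list(dist.ids), labels, k, seed)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels by order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def call_related(assign: ClusterAssignment, query_id: str) -> AssociationResult:
    """Diseases sharing the query's cluster, minus the query itself."""
    if query_id not in assign.ids:
        raise ValueError(f"query disease {query_id} absent from clustering")
    label = assign.label_of(query_id)
    related = assign.members(label) - {query_id}
    return AssociationResult(
        query_id=query_id,
        related=related,
        parameters={"k": assign.k, "seed": assign.seed},
    )


def run_pipeline(
    corpus: AnnotationCorpus,
    query_id: str,
    config: PipelineConfig,
    disease_universe: Sequence[str] | None = None,
) -> AssociationResult:
    """End-to-end disease association for a query disease.

    Raises ``ValueError`` if the query is dropped by the matrix filters.
    The returned parameters echo the config plus the selected rank, the
    retained disease ids, and SHA-256 checksums of intermediate arrays.
    """
    universe = list(disease_universe) if disease_universe else corpus.disease_universe
    fingerprints = [
        build_fingerprint(
            corpus,
            d,
            p_cutoff=config.p_cutoff,
            tail=config.p_tail,
            log_base=config.log_base,
        )
        for d in universe
    ]
    matrix = build_matrix(
        fingerprints,
        min_genes=config.min_genes,
        count_after_gene_filter=config.count_after_gene_filter,
    )
    approx, model = lowrank.approximate(
        matrix,
        energy_target=config.energy_target,
        mode=config.energy_mode,
        rank=config.rank,
    )
    dist = spearman_distance(approx, ids=matrix.row_ids)
    assign = spectral_cluster(dist, k=config.k, seed=config.seed)
    result = call_related(assign, query_id)
    result.parameters = {
        **config.to_dict(),
        "r": model.rank_selected,
        "energy_fraction": model.energy_fraction,
        "retained_ids": list(matrix.row_ids),
        "cluster_labels": {d: int(l) for d, l in zip(assign.ids, assign.labels)},
        "checksums": {
            "matrix": _sha256(matrix.values),
            "approximation": _sha256(approx),
            "distances": _sha256(dist.values),
        },
    }
    return result


def _sha256(array: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(array).tobytes()).hexdigest()


def distance_to_tsv(dist: DistanceMatrix, path: str | Path) -> None:
    """Square TSV export with an id header row and id first column."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("disease_id\t" + "\t".join(dist.ids) + "\n")
        for disease_id, row in zip(dist.ids, dist.values):
            handle.write(
                disease_id + "\t" + "\t".join(repr(float(v)) for v in row) + "\n"
            )
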