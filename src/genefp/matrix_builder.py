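"""Assemble the disease x gene weight matrix and apply the two row/column filters.

Filters: genes present in only one retained disease are dropped, and diseases
whose fingerprint holds fewer than ``min_genes`` genes are dropped. Both are
applied until a fixed point so the final matrix satisfies both conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse

from .fingerprint import GeneFingerprint

log = logging.getLogger(__name__)

#: Fewer rows than this makes downstream clustering undefined.
MIN_ROWS = 3


@dataclass
class DiseaseGeneMatrix:
    """Dense nonnegative weight matrix with ordered row/column identifiers."""

    row_ids: list[str]
    col_ids: list[int]
    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, disease_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(disease_id)]


def build_matrix(
    fingerprints: Iterable[GeneFingerprint],
    min_genes: int = 1,
    count_after_gene_filter: bool = False,
) -> DiseaseGeneMatrix:
    """Build the filtered disease x gene matrix from per-disease fingerprints.

    By default the minimum-gene requirement is evaluated on the raw
    fingerprint size; with ``count_after_gene_filter=True`` it is re-evaluated
    on the surviving columns, and both filters iterate to a joint fixed point.
    Raises ``ValueError`` if fewer than 3 diseases remain.
    """
    if min_genes < 1:
        raise ValueError(f"min_genes must be >= 1, got {min_genes}")

    fps = sorted(fingerprints, key=lambda fp: fp.disease_id)
    if len({fp.disease_id for fp in fps}) != len(fps):
        raise ValueError("duplicate disease_id among fingerprints")

    weights = {fp.disease_id: fp.weights() for fp in fps}
    retained = [fp.disease_id for fp in fps if fp.m >= min_genes]
    dropped = [fp.disease_id for fp in fps if fp.disease_id not in set(retained)]
    if dropped:
        log.info("min_genes=%d drops %d diseases: %s", min_genes, len(dropped), dropped)

    genes = _shared_genes(weights, retained)
    if count_after_gene_filter:
        while True:
            kept = [
                d for d in retained if len(set(weights[d]) & genes) >= min_genes
            ]
            new_genes = _shared_genes(weights, kept)
            if kept == retained and new_genes == genes:
                break
            retained, genes = kept, new_genes
    # with the pre-filter count the disease set is final after one pass and
    # _shared_genes already reflects it, so no iteration is needed

    if len(retained) < MIN_ROWS:
        raise ValueError(
            f"only {len(retained)} diseases remain after filtering "
            f"(min_genes={min_genes}); need >= {MIN_ROWS}"
        )

    col_ids = sorted(genes)
    values = np.zeros((len(retained), len(col_ids)), dtype=float)
    col_index = {g: j for j, g in enumerate(col_ids)}
    for i, disease_id in enumerate(retained):
        for gene, weight in weights[disease_id].items():
            j = col_index.get(gene)
            if j is not None:
                values[i, j] = weight
    return DiseaseGeneMatrix(row_ids=list(retained), col_ids=col_ids, values=values)


def _shared_genes(
    weights: dict[str, dict[int, float]], diseases: Sequence[str]
) -> set[int]:
    """Genes appearing in >= 2 of the given diseases' fingerprints."""
    counts: dict[int, int] = {}
    for d in diseases:
        for gene in weights[d]:
            counts[gene] = counts.get(gene, 0) + 1
    return {g for g, c in counts.items() if c >= 2}


def matrix_to_tsv(matrix: DiseaseGeneMatrix, path: str | Path) -> None:
    """Write the matrix as TSV: header of gene ids, first column disease ids."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("disease_id\t" + "\t".join(str(g) for g in matrix.col_ids) + "\n")
        for disease_id, row in zip(matrix.row_ids, matrix.values):
            handle.write(
                disease_id + "\t" + "\t".join(repr(float(v)) for v in row) + "\n"
            )


def matrix_from_tsv(path: str | Path) -> DiseaseGeneMatrix:
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if not header or header[0] != "disease_id":
            raise ValueError(f"{path}: missing disease_id header column")
        col_ids = [int(g) for g in header[1:]]
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for raw in handle:
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(col_ids) + 1:
                raise ValueError(f"{path}: ragged row for {fields[0]!r}")
            row_ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    return DiseaseGeneMatrix(row_ids, col_ids, np.asarray(rows, dtype=float))


def matrix_to_mtx(matrix: DiseaseGeneMatrix, path: str | Path) -> None:
    """Write a MatrixMarket coordinate export plus ``.rows``/``.cols`` sidecars."""
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values))
    path.with_suffix(path.suffix + ".rows").write_text(
        "".join(f"{d}\n" for d in matrix.row_ids), encoding="utf-8"
    )
    path.with_suffix(path.suffix + ".cols").write_text(
        "".join(f"{g}\n" for g in matrix.col_ids), encoding="utf-8"
    )
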