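"""Per-disease gene fingerprints from hypergeometric over-representation.

A disease is represented as the set of genes that co-occur with it in the
annotated literature, each weighted by ``-log(p)`` of the hypergeometric
enrichment test on the 2x2 co-occurrence table:

====  ============================  ======================
      disease                       not disease
====  ============================  ======================
gene  k (both)                      K - k
not   n - k                         N - K - n + k
====  ============================  ======================

with K = PMIDs mentioning the gene, n = PMIDs for the disease and N = total
PMIDs in the corpus universe. Only genes with k >= 1 enter a fingerprint.
"""

from __future__ import annotations

import json
import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from scipy.stats import hypergeom

from .corpus_io import AnnotationCorpus

log = logging.getLogger(__name__)

#: Smallest positive normal double; p-values underflowing to 0 are floored
#: here before taking the log.
P_FLOOR = sys.float_info.min


@dataclass(frozen=True)
class EnrichmentCounts:
    """Co-occurrence counts (k, K, n, N) for one (gene, disease) pair."""

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        k, K, n, N = self.k, self.K, self.n, self.N
        if min(k, K, n, N) < 0:
            raise ValueError(f"negative count in {self}")
        if K > N or n > N:
            raise ValueError(f"K and n must not exceed N: {self}")
        if k > min(K, n) or k < max(0, n + K - N):
            raise ValueError(
                f"k={k} outside hypergeometric support "
                f"[{max(0, n + K - N)}, {min(K, n)}] for K={K}, n={n}, N={N}"
            )


class FingerprintEntry(NamedTuple):
    counts: EnrichmentCounts
    p_value: float
    weight: float


@dataclass
class GeneFingerprint:
    """Map gene_id -> (counts, p-value, weight) for a single disease."""

    disease_id: str
    entries: dict[int, FingerprintEntry] = field(default_factory=dict)

    @property
    def m(self) -> int:
        """Number of associated genes."""
        return len(self.entries)

    def weights(self) -> dict[int, float]:
        return {gene: entry.weight for gene, entry in self.entries.items()}


def hypergeom_pmf(counts: EnrichmentCounts) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n): C(K,k)C(N-K,n-k)/C(N,n)."""
    p = float(hypergeom.pmf(counts.k, counts.N, counts.K, counts.n))
    return min(max(p, 0.0), 1.0)


def enrichment_pvalue(counts: EnrichmentCounts, tail: str = "upper") -> float:
    """Over-representation p-value for the observed co-occurrence.

    ``tail="upper"`` (default) returns P(X >= k), the standard enrichment
    tail; ``tail="pmf"`` returns the point mass P(X = k).
    """
    if tail == "upper":
        # sf(k-1) = P(X > k-1) = P(X >= k)
        p = float(hypergeom.sf(counts.k - 1, counts.N, counts.K, counts.n))
    elif tail == "pmf":
        p = float(hypergeom.pmf(counts.k, counts.N, counts.K, counts.n))
    else:
        raise ValueError(f"tail must be 'upper' or 'pmf', got {tail!r}")
    return min(max(p, 0.0), 1.0)


def build_fingerprint(
    corpus: AnnotationCorpus,
    disease_id: str,
    p_cutoff: float | None = None,
    tail: str = "upper",
    log_base: float = 10.0,
) -> GeneFingerprint:
    """Build the fingerprint of one disease from the annotation corpus.

    One entry per gene co-occurring with the disease on >= 1 PMID (and with
    p <= ``p_cutoff`` when a cutoff is given); ``weight = -log_base(p)``,
    with p floored at the smallest positive normal double on underflow.
    """
    if disease_id not in corpus.disease_universe:
        raise ValueError(f"{disease_id} is not in the corpus disease universe")
    if log_base <= 1.0:
        raise ValueError(f"log_base must exceed 1, got {log_base}")

    disease_pmids = corpus.disease_pmids(disease_id)
    n = len(disease_pmids)
    if n == 0:
        log.info("disease %s has no annotated PMIDs; empty fingerprint", disease_id)
        return GeneFingerprint(disease_id)

    k_counts: dict[int, int] = {}
    for pmid in disease_pmids:
        for gene in corpus.pmid_to_genes.get(pmid, ()):
            k_counts[gene] = k_counts.get(gene, 0) + 1

    entries: dict[int, FingerprintEntry] = {}
    for gene, k in sorted(k_counts.items()):
        counts = EnrichmentCounts(
            k=k, K=len(corpus.gene_pmids(gene)), n=n, N=corpus.N_universe
        )
        p = enrichment_pvalue(counts, tail=tail)
        if p <= 0.0:
            log.warning(
                "p-value underflow for gene %d in %s; floored at %.3e",
                gene,
                disease_id,
                P_FLOOR,
            )
            p = P_FLOOR
        if p_cutoff is not None and p > p_cutoff:
            continue
        weight = -math.log(p, log_base)
        entries[gene] = FingerprintEntry(counts, p, weight)
    return GeneFingerprint(disease_id, entries)


def build_fingerprints(
    corpus: AnnotationCorpus,
    p_cutoff: float | None = None,
    tail: str = "upper",
    log_base: float = 10.0,
) -> list[GeneFingerprint]:
    """Fingerprints for every disease in the corpus universe, in order."""
    return [
        build_fingerprint(corpus, d, p_cutoff=p_cutoff, tail=tail, log_base=log_base)
        for d in corpus.disease_universe
    ]


def select_highly_relevant_genes(
    fp: GeneFingerprint, cutoff: float, strict: bool = True
) -> list[int]:
    """Genes with p-value below ``cutoff``, sorted by gene id.

    The comparison is strict (<) by default; pass ``strict=False`` for <=.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if strict:
        keep = (g for g, e in fp.entries.items() if e.p_value < cutoff)
    else:
        keep = (g for g, e in fp.entries.items() if e.p_value <= cutoff)
    return sorted(keep)


_TSV_HEADER = "disease_id\tgene_id\tk\tK\tn\tN\tp_value\tweight"


def fingerprints_to_tsv(
    fingerprints: Iterable[GeneFingerprint], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_TSV_HEADER + "\n")
        for fp in fingerprints:
            for gene in sorted(fp.entries):
                c, p, w = fp.entries[gene]
                handle.write(
                    f"{fp.disease_id}\t{gene}\t{c.k}\t{c.K}\t{c.n}\t{c.N}"
                    f"\t{p!r}\t{w!r}\n"
                )


def fingerprints_from_tsv(path: str | Path) -> list[GeneFingerprint]:
    by_disease: dict[str, GeneFingerprint] = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"{path}: unexpected fingerprint header {header!r}")
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns")
            disease_id, gene, k, K, n, N, p, w = fields
            fp = by_disease.setdefault(disease_id, GeneFingerprint(disease_id))
            counts = EnrichmentCounts(int(k), int(K), int(n), int(N))
            fp.entries[int(gene)] = FingerprintEntry(counts, float(p), float(w))
    return list(by_disease.values())


def fingerprints_to_json(fingerprints: Iterable[GeneFingerprint]) -> str:
    payload = {
        fp.disease_id: {
            str(gene): {
                "k": e.counts.k,
                "K": e.counts.K,
                "n": e.counts.n,
                "N": e.counts.N,
                "p_value": e.p_value,
                "weight": e.weight,
            }
            for gene, e in sorted(fp.entries.items())
        }
        for fp in fingerprints
    }
    return json.dumps(payload, indent=2, sort_keys=True)
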