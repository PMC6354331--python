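"""Readers, writers and assembly for the literature-annotation corpus.

Input formats
-------------
gene2pubmed
    NCBI-style 3-column TSV ``tax_id <TAB> GeneID <TAB> PubMed_ID`` with
    ``#``-prefixed header/comment lines.
disease2pubmed
    2-column TSV ``pmid <TAB> descriptor-UI`` (no header, UTF-8); a simple
    exchange format equivalent to the MeSH headings extracted from PubMed XML.
PubMed XML
    MedlineCitation elements; only ``PMID`` and
    ``MeshHeadingList/MeshHeading/DescriptorName@UI`` are consumed.
MeSH tree
    3-column TSV ``UI <TAB> preferred-name <TAB> tree-numbers`` where tree
    numbers are semicolon-joined dotted codes such as ``C08.381.495``.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

log = logging.getLogger(__name__)

HUMAN_TAX_ID = 9606

_TREE_CODE_RE = re.compile(r"^[A-Z]\d+(\.\d+)*$")


class CorpusFormatError(ValueError):
    """Raised when an input file violates its declared format."""


class GenePubmedRecord(NamedTuple):
    tax_id: int
    gene_id: int
    pmid: int


class DiseasePubmedRecord(NamedTuple):
    pmid: int
    disease_id: str


@dataclass(frozen=True)
class MeshTreeEntry:
    """One vocabulary descriptor with its tree positions."""

    disease_id: str
    name: str
    tree_numbers: tuple[str, ...]


@dataclass
class AnnotationCorpus:
    """Bipartite PMID->genes and PMID->diseases maps over a disease universe.

    ``N_universe`` is the number of distinct PMIDs carrying at least one
    disease from the universe (or, when built unrestricted, all PMIDs seen).
    """

    pmid_to_genes: dict[int, set[int]]
    pmid_to_diseases: dict[int, set[str]]
    disease_universe: list[str]
    N_universe: int
    _disease_index: dict[str, set[int]] | None = field(
        default=None, repr=False, compare=False
    )
    _gene_index: dict[int, set[int]] | None = field(
        default=None, repr=False, compare=False
    )

    def disease_pmids(self, disease_id: str) -> set[int]:
        """PMIDs annotated with ``disease_id`` (empty set if none)."""
        if self._disease_index is None:
            index: dict[str, set[int]] = {d: set() for d in self.disease_universe}
            for pmid, diseases in self.pmid_to_diseases.items():
                for d in diseases:
                    index.setdefault(d, set()).add(pmid)
            self._disease_index = index
        return self._disease_index.get(disease_id, set())

    def gene_pmids(self, gene_id: int) -> set[int]:
        """PMIDs annotated with ``gene_id`` (empty set if none)."""
        if self._gene_index is None:
            index: dict[int, set[int]] = {}
            for pmid, genes in self.pmid_to_genes.items():
                for g in genes:
                    index.setdefault(g, set()).add(pmid)
            self._gene_index = index
        return self._gene_index.get(gene_id, set())


def read_gene2pubmed(
    path: str | Path, tax_id_filter: int = HUMAN_TAX_ID
) -> list[GenePubmedRecord]:
    """Read a gene2pubmed TSV, keeping records for one taxon, de-duplicated.

    Raises :class:`CorpusFormatError` naming the offending line on malformed
    input; logs a warning and returns ``[]`` when nothing survives the filter.
    """
    records: list[GenePubmedRecord] = []
    seen: set[tuple[int, int]] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                tax_id, gene_id, pmid = (int(f) for f in fields)
            except ValueError as exc:
                raise CorpusFormatError(
                    f"{path}:{lineno}: non-integer field in {fields!r}"
                ) from exc
            if tax_id != tax_id_filter:
                continue
            key = (gene_id, pmid)
            if key in seen:
                continue
            seen.add(key)
            records.append(GenePubmedRecord(tax_id, gene_id, pmid))
    if not records:
        log.warning("no gene2pubmed records for tax_id=%d in %s", tax_id_filter, path)
    return records


def read_disease2pubmed(path: str | Path) -> list[DiseasePubmedRecord]:
    """Read the 2-column (pmid, descriptor UI) TSV, de-duplicated."""
    records: list[DiseasePubmedRecord] = []
    seen: set[tuple[int, str]] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                pmid = int(fields[0])
            except ValueError as exc:
                raise CorpusFormatError(
                    f"{path}:{lineno}: malformed pmid {fields[0]!r}"
                ) from exc
            disease_id = fields[1].strip()
            key = (pmid, disease_id)
            if key in seen:
                continue
            seen.add(key)
            records.append(DiseasePubmedRecord(pmid, disease_id))
    return records


def extract_mesh_from_pubmed_xml(path: str | Path) -> list[DiseasePubmedRecord]:
    """Extract (PMID, descriptor UI) pairs from MedlineCitation-style XML.

    Parsing is streaming (elements are discarded after use) so full baseline
    files remain tractable. Descriptors missing a UI attribute are skipped
    with a logged warning; citations without MeSH headings contribute nothing.
    """
    records: list[DiseasePubmedRecord] = []
    seen: set[tuple[int, str]] = set()
    try:
        for _event, elem in ET.iterparse(str(path), events=("end",)):
            if elem.tag != "MedlineCitation":
                continue
            pmid_elem = elem.find("PMID")
            if pmid_elem is None or pmid_elem.text is None:
                log.warning("MedlineCitation without PMID in %s; skipped", path)
                elem.clear()
                continue
            pmid = int(pmid_elem.text.strip())
            for descriptor in elem.iter("DescriptorName"):
                ui = descriptor.get("UI")
                if ui is None:
                    log.warning(
                        "DescriptorName without UI attribute for PMID %d; skipped",
                        pmid,
                    )
                    continue
                key = (pmid, ui)
                if key not in seen:
                    seen.add(key)
                    records.append(DiseasePubmedRecord(pmid, ui))
            elem.clear()
    except ET.ParseError as exc:
        raise CorpusFormatError(f"unparseable XML in {path}: {exc}") from exc
    return records


def read_mesh_tree(path: str | Path) -> list[MeshTreeEntry]:
    """Read the 3-column vocabulary tree TSV (UI, name, ;-joined tree codes)."""
    entries: list[MeshTreeEntry] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            ui, name, joined = fields
            codes = tuple(c.strip() for c in joined.split(";") if c.strip())
            for code in codes:
                if not _TREE_CODE_RE.match(code):
                    raise CorpusFormatError(
                        f"{path}:{lineno}: malformed tree number {code!r}"
                    )
            entries.append(MeshTreeEntry(ui.strip(), name.strip(), codes))
    return entries


def select_branch(
    entries: Iterable[MeshTreeEntry], branch_code: str
) -> list[str]:
    """Descriptor UIs at or strictly under a dotted tree prefix, sorted.

    ``C08.381`` matches ``C08.381`` and ``C08.381.495`` but not ``C08.3811``
    (segment boundaries are respected).
    """
    prefix = branch_code + "."
    matched = {
        e.disease_id
        for e in entries
        if any(code == branch_code or code.startswith(prefix) for code in e.tree_numbers)
    }
    if not matched:
        log.warning("no descriptors under branch %s", branch_code)
    return sorted(matched)


def build_corpus(
    gene_records: Iterable[GenePubmedRecord],
    disease_records: Iterable[DiseasePubmedRecord],
    disease_universe: Sequence[str],
    restrict_to_universe: bool = True,
) -> AnnotationCorpus:
    """Assemble an :class:`AnnotationCorpus` over a disease universe.

    With ``restrict_to_universe`` (default) all downstream counts are taken
    within the set of PMIDs that carry at least one universe disease: gene
    annotations on PMIDs outside that set are discarded and ``N_universe`` is
    the size of that set. With ``restrict_to_universe=False`` every gene
    annotation is kept and ``N_universe`` counts all PMIDs seen in either map.
    """
    if not disease_universe:
        raise ValueError("disease_universe must be non-empty")
    universe = list(dict.fromkeys(disease_universe))
    universe_set = set(universe)

    pmid_to_diseases: dict[int, set[str]] = {}
    for pmid, disease_id in disease_records:
        if disease_id in universe_set:
            pmid_to_diseases.setdefault(pmid, set()).add(disease_id)
    universe_pmids = set(pmid_to_diseases)

    pmid_to_genes: dict[int, set[int]] = {}
    for record in gene_records:
        if restrict_to_universe and record.pmid not in universe_pmids:
            continue
        pmid_to_genes.setdefault(record.pmid, set()).add(record.gene_id)

    if restrict_to_universe:
        n_universe = len(universe_pmids)
    else:
        n_universe = len(universe_pmids | set(pmid_to_genes))

    annotated = {d for diseases in pmid_to_diseases.values() for d in diseases}
    for disease_id in universe:
        if disease_id not in annotated:
            log.info("universe disease %s has zero annotated PMIDs", disease_id)

    return AnnotationCorpus(
        pmid_to_genes=pmid_to_genes,
        pmid_to_diseases=pmid_to_diseases,
        disease_universe=universe,
        N_universe=n_universe,
    )


def write_gene2pubmed(
    pmid_to_genes: Mapping[int, set[int]],
    path: str | Path,
    tax_id: int = HUMAN_TAX_ID,
) -> None:
    """Write a PMID->genes map in gene2pubmed format (sorted, deterministic)."""
    rows = sorted(
        (tax_id, gene, pmid)
        for pmid, genes in pmid_to_genes.items()
        for gene in genes
    )
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#Format: tax_id GeneID PubMed_ID (tab is used as a separator)\n")
        for tax, gene, pmid in rows:
            handle.write(f"{tax}\t{gene}\t{pmid}\n")


def write_disease2pubmed(
    pmid_to_diseases: Mapping[int, set[str]], path: str | Path
) -> None:
    """Write a PMID->diseases map in the 2-column exchange format (sorted)."""
    rows = sorted(
        (pmid, disease)
        for pmid, diseases in pmid_to_diseases.items()
        for disease in diseases
    )
    with open(path, "w", encoding="utf-8") as handle:
        for pmid, disease in rows:
            handle.write(f"{pmid}\t{disease}\n")


def write_mesh_tree(entries: Iterable[MeshTreeEntry], path: str | Path) -> None:
    """Write vocabulary entries in the 3-column tree TSV format (sorted)."""
    with open(path, "w", encoding="utf-8") as handle:
        for entry in sorted(entries, key=lambda e: e.disease_id):
            handle.write(
                f"{entry.disease_id}\t{entry.name}\t{';'.join(entry.tree_numbers)}\n"
            )
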