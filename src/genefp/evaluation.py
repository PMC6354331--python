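"""Scoring against expert labels and hyperparameter tuning.

Diseases labeled ``undefined`` take part in the unsupervised stages (they stay
in the matrix and the clustering) but are excluded from the confusion counts;
they are the prediction target of :func:`predict_undefined`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .association import PipelineConfig, run_pipeline
from .corpus_io import AnnotationCorpus

log = logging.getLogger(__name__)

RELATED = "related"
NON_RELATED = "non_related"
UNDEFINED = "undefined"
LABELS = (RELATED, NON_RELATED, UNDEFINED)
VOTES_PER_DISEASE = 5


@dataclass
class ExpertLabels:
    """Expert consensus labels of diseases w.r.t. a query disease."""

    query_id: str
    labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.query_id in self.labels:
            raise ValueError(f"query disease {self.query_id} must not be labeled")
        bad = {l for l in self.labels.values() if l not in LABELS}
        if bad:
            raise ValueError(f"unknown labels {bad}; expected one of {LABELS}")

    def of_class(self, label: str) -> set[str]:
        return {d for d, l in self.labels.items() if l == label}


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f_score: float
    parameters: dict = field(default_factory=dict)


def aggregate_expert_votes(
    votes: Mapping[str, Sequence[str]], query_id: str
) -> ExpertLabels:
    """Consensus: related iff >= 4 of 5 'related' votes, non-related iff >= 3
    'non_related' votes, undefined otherwise."""
    labels: dict[str, str] = {}
    for disease_id, vote_list in votes.items():
        if len(vote_list) != VOTES_PER_DISEASE:
            raise ValueError(
                f"{disease_id}: expected {VOTES_PER_DISEASE} votes, "
                f"got {len(vote_list)}"
            )
        bad = [v for v in vote_list if v not in (RELATED, NON_RELATED)]
        if bad:
            raise ValueError(f"{disease_id}: invalid votes {bad}")
        n_related = sum(v == RELATED for v in vote_list)
        n_non = VOTES_PER_DISEASE - n_related
        if n_related >= 4:
            labels[disease_id] = RELATED
        elif n_non >= 3:
            labels[disease_id] = NON_RELATED
        else:
            labels[disease_id] = UNDEFINED
    return ExpertLabels(query_id=query_id, labels=labels)


def harmonic_f(precision: float, recall: float) -> float:
    """F1, the harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def score(
    predicted_related: Iterable[str],
    labels: ExpertLabels,
    parameters: dict | None = None,
) -> EvaluationReport:
    """Precision/recall/F1 of a predicted related set against the labels.

    Undefined-labeled diseases never enter the confusion counts. Zero
    denominators yield 0 with a warning.
    """
    predicted = set(predicted_related)
    related = labels.of_class(RELATED)
    non_related = labels.of_class(NON_RELATED)
    tp = len(predicted & related)
    fp = len(predicted & non_related)
    fn = len(related - predicted)
    tn = len(non_related - predicted)
    if tp + fp == 0:
        log.warning("no labeled predictions; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        log.warning("no related-labeled diseases; recall set to 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    return EvaluationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=precision,
        recall=recall,
        f_score=harmonic_f(precision, recall),
        parameters=dict(parameters or {}),
    )


DEFAULT_GRID: dict[str, list] = {
    "energy_target": [0.95],
    "energy_mode": ["sum", "sum_of_squares"],
    "k": [2, 3, 4],
    "min_genes": [1],
}


def tune(
    corpus: AnnotationCorpus,
    labels: ExpertLabels,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
    base_config: PipelineConfig | None = None,
) -> tuple[PipelineConfig, EvaluationReport, list[tuple[PipelineConfig, EvaluationReport]]]:
    """Exhaustive grid search maximizing F1 on the labeled diseases.

    Grid keys: ``energy_target``, ``energy_mode``, ``k``, ``min_genes`` and
    optionally ``rank`` (explicit rank lists override the energy rule). Ties
    are broken by smaller selected rank, then smaller k. Configs that fail
    (e.g. filters leave too few diseases, or drop the query) are skipped;
    an error is raised if every config fails. Returns the winning config,
    its report, and the full leaderboard.
    """
    grid = dict(grid or DEFAULT_GRID)
    if not all(len(v) > 0 for v in grid.values()) or not grid:
        raise ValueError("grid must be non-empty with non-empty value lists")
    if not labels.of_class(RELATED) or not labels.of_class(NON_RELATED):
        raise ValueError("labels must contain >= 1 related and >= 1 non_related")
    base = base_config or PipelineConfig()

    keys = sorted(grid)
    leaderboard: list[tuple[PipelineConfig, EvaluationReport]] = []
    for combo in itertools.product(*(grid[key] for key in keys)):
        overrides = dict(zip(keys, combo))
        config = PipelineConfig(
            **{
                **base.to_dict(),
                **overrides,
                "seed": seed,
            }
        )
        try:
            result = run_pipeline(corpus, labels.query_id, config)
        except ValueError as exc:
            log.info("config %s degenerate: %s", overrides, exc)
            continue
        report = score(result.related, labels, parameters=result.parameters)
        leaderboard.append((config, report))

    if not leaderboard:
        raise ValueError("every configuration in the grid was degenerate")

    def sort_key(item: tuple[PipelineConfig, EvaluationReport]):
        config, report = item
        return (-report.f_score, report.parameters.get("r", 0), config.k)

    leaderboard.sort(key=sort_key)
    best_config, best_report = leaderboard[0]
    return best_config, best_report, leaderboard


def predict_undefined(
    corpus: AnnotationCorpus,
    labels: ExpertLabels,
    best_config: PipelineConfig,
) -> set[str]:
    """Undefined-labeled diseases falling in the query's cluster at the
    chosen configuration. Undefined diseases dropped by the matrix filters
    are excluded and logged."""
    result = run_pipeline(corpus, labels.query_id, best_config)
    undefined = labels.of_class(UNDEFINED)
    retained = set(result.parameters.get("retained_ids", ()))
    dropped = undefined - retained
    if dropped:
        log.info(
            "undefined diseases dropped by filters (min_genes=%d): %s",
            best_config.min_genes,
            sorted(dropped),
        )
    return undefined & result.related


def read_labels(path: str | Path, query_id: str) -> ExpertLabels:
    """Read a 2-column TSV (disease_id, label) into :class:`ExpertLabels`."""
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            labels[fields[0]] = fields[1]
    return ExpertLabels(query_id=query_id, labels=labels)


def write_labels(labels: ExpertLabels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for disease_id in sorted(labels.labels):
            handle.write(f"{disease_id}\t{labels.labels[disease_id]}\n")


def read_votes(path: str | Path) -> dict[str, list[str]]:
    """Read a votes TSV: disease_id followed by 5 vote columns."""
    votes: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 1 + VOTES_PER_DISEASE:
                raise ValueError(
                    f"{path}:{lineno}: expected disease id plus "
                    f"{VOTES_PER_DISEASE} votes"
                )
            votes[fields[0]] = fields[1:]
    return votes
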