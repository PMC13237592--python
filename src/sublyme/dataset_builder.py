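"""Labelled training-set construction.

Positives (lysins) come from a curated source and keep all homology-cluster
members; negatives (non-lysins) are obtained by annotation-exclusion
filtering — drop proteins with no annotation or any lysin-related term —
followed by per-cluster dereplication down to one randomly chosen
representative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from sublyme.io_formats import ClusterAssignment, EmbeddingStore

__all__ = [
    "AnnotationTable",
    "LabelledDataset",
    "default_exclusion_terms",
    "read_annotation_tsv",
    "read_exclusion_terms",
    "filter_nonlysin_candidates",
    "select_cluster_representatives",
    "assemble_dataset",
]


@dataclass
class AnnotationTable:
    """Protein id -> set of free-text functional annotation terms."""

    terms: dict[str, set[str]]

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, protein_id: str) -> set[str]:
        return self.terms[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.terms


@dataclass
class LabelledDataset:
    """Embeddings + binary labels + homology-cluster ids — the unit of
    training and evaluation.

    ``labels`` maps every id to 0/1 (task 1: lysin=1; task 2: endolysin=1,
    VAL=0); ``clusters`` maps every id to its cluster.  Both must cover
    every id in the dataset.
    """

    store: EmbeddingStore
    labels: dict[str, int]
    clusters: dict[str, str]

    def __post_init__(self) -> None:
        ids = set(self.store.ids)
        missing_label = ids - set(self.labels)
        missing_cluster = ids - set(self.clusters)
        if missing_label:
            raise ValueError(
                f"labels missing for ids: {sorted(missing_label)[:5]}..."
                if len(missing_label) > 5
                else f"labels missing for ids: {sorted(missing_label)}"
            )
        if missing_cluster:
            raise ValueError(f"clusters missing for {len(missing_cluster)} ids")

    @property
    def ids(self) -> list[str]:
        return self.store.ids

    def __len__(self) -> int:
        return len(self.store)

    def X(self, ids: Iterable[str] | None = None) -> np.ndarray:
        return self.store.matrix(self.ids if ids is None else ids)

    def y(self, ids: Iterable[str] | None = None) -> np.ndarray:
        ids = self.ids if ids is None else list(ids)
        return np.array([self.labels[i] for i in ids], dtype=int)

    def groups(self, ids: Iterable[str] | None = None) -> list[str]:
        ids = self.ids if ids is None else list(ids)
        return [self.clusters[i] for i in ids]

    def subset(self, ids: Iterable[str]) -> "LabelledDataset":
        ids = list(ids)
        return LabelledDataset(
            self.store.subset(ids),
            {i: self.labels[i] for i in ids},
            {i: self.clusters[i] for i in ids},
        )

    def is_trainable(self) -> bool:
        return len(set(self.labels[i] for i in self.ids)) == 2


def default_exclusion_terms() -> list[str]:
    """The packaged lysin-related exclusion term list (lowercase)."""
    text = (
        resources.files("sublyme").joinpath("data/exclusion_terms.txt").read_text()
    )
    return _parse_terms(text)


def read_exclusion_terms(path: str | Path) -> list[str]:
    """One term per line; ``#`` lines and blanks ignored."""
    return _parse_terms(Path(path).read_text())


def _parse_terms(text: str) -> list[str]:
    terms = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.append(line.lower())
    return terms


def read_annotation_tsv(path: str | Path) -> AnnotationTable:
    """Two-column TSV (protein id, term); repeated rows accumulate terms.

    An id appearing with an empty term column is recorded with no terms,
    so unannotated proteins can be represented explicitly.
    """
    table: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 1 or not row[0]:
                raise ValueError(f"line {lineno}: missing protein id")
            pid = row[0]
            table.setdefault(pid, set())
            term = row[1].strip() if len(row) > 1 else ""
            if term:
                table[pid].add(term)
    return AnnotationTable(table)


def filter_nonlysin_candidates(
    table: AnnotationTable, exclusion_terms: Iterable[str] | None = None
) -> set[str]:
    """Retain proteins safe to use as non-lysin negatives.

    A protein is retained iff it has at least one annotation term AND no
    term contains (case-insensitive substring match) any exclusion term.
    Unannotated proteins are removed: absence of annotation is no evidence
    of absence of lytic function.
    """
    terms = [t.lower() for t in (
        default_exclusion_terms() if exclusion_terms is None else list(exclusion_terms)
    )]
    if not terms:
        raise ValueError("exclusion term list must be non-empty")
    retained: set[str] = set()
    for pid, annots in table.terms.items():
        if not annots:
            continue
        lowered = [a.lower() for a in annots]
        if any(excl in a for a in lowered for excl in terms):
            continue
        retained.add(pid)
    return retained


def select_cluster_representatives(
    assignment: ClusterAssignment, seed: int
) -> dict[str, str]:
    """One uniformly chosen member per cluster (seeded, deterministic).

    Returns cluster id -> selected member id.
    """
    if len(assignment) == 0:
        raise ValueError("cluster assignment is empty")
    rng = np.random.default_rng(seed)
    chosen: dict[str, str] = {}
    for cluster, members in sorted(assignment.clusters().items()):
        chosen[cluster] = members[rng.integers(len(members))]
    return chosen


def assemble_dataset(
    positives: set[str],
    negatives: set[str],
    embeddings: EmbeddingStore,
    clusters: ClusterAssignment,
) -> LabelledDataset:
    """Combine labelled id sets with their embeddings and cluster ids.

    Positives are taken as supplied — all cluster members, no dereplication;
    negatives are the (already dereplicated) representative set.  The same
    code path serves task 2 with endolysins as positives and VALs as
    negatives.
    """
    overlap = positives & negatives
    if overlap:
        raise ValueError(
            f"ids present in both label sets: {sorted(overlap)[:5]}"
        )
    all_ids = sorted(positives) + sorted(negatives)
    missing_emb = [i for i in all_ids if i not in embeddings]
    if missing_emb:
        raise ValueError(f"ids lacking an embedding: {missing_emb[:5]}")
    missing_clu = [i for i in all_ids if i not in clusters]
    if missing_clu:
        raise ValueError(f"ids lacking a cluster: {missing_clu[:5]}")
    labels = {i: 1 for i in positives}
    labels.update({i: 0 for i in negatives})
    cluster_map = {i: clusters.cluster_of(i) for i in all_ids}
    return LabelledDataset(embeddings.subset(all_ids), labels, cluster_map)
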