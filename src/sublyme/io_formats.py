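"""Readers and writers for every external format the pipeline touches.

All other modules consume only the types defined here: protein records
(FASTA), homology cluster assignments (MMseqs2 ``createtsv`` dialect),
InterProScan domain hits, keyed embedding stores (HDF5), and the output
predictions table.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "ClusterAssignment",
    "DomainHit",
    "EmbeddingStore",
    "read_fasta",
    "write_fasta",
    "read_cluster_tsv",
    "read_interproscan_tsv",
    "read_embedding_store",
    "write_embedding_store",
    "write_predictions_tsv",
    "read_predictions_tsv",
]

#: residues accepted in input sequences: the 20 canonical letters plus the
#: common ambiguity/rare codes emitted by gene callers.
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identifier and free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ClusterAssignment:
    """Partition of proteins into homology clusters.

    ``member_to_cluster`` maps every member id to exactly one cluster id.
    When derived from an MMseqs2 TSV the cluster ids are the representative
    ids and every representative maps to itself.  The ``level`` tag records
    the clustering stringency: "standard" for sequence-level clustering at
    30% identity / 70% coverage, "remote" for profile-level remote homology
    clusters.
    """

    member_to_cluster: dict[str, str]
    level: str = "standard"

    def clusters(self) -> dict[str, list[str]]:
        """Cluster id -> sorted member list."""
        out: dict[str, list[str]] = {}
        for member, cluster in self.member_to_cluster.items():
            out.setdefault(cluster, []).append(member)
        for members in out.values():
            members.sort()
        return out

    def cluster_of(self, member: str) -> str:
        try:
            return self.member_to_cluster[member]
        except KeyError:
            raise KeyError(f"no cluster recorded for protein {member!r}") from None

    def __len__(self) -> int:
        return len(self.member_to_cluster)

    def __contains__(self, member: str) -> bool:
        return member in self.member_to_cluster


@dataclass(frozen=True)
class DomainHit:
    """One signature match from a domain-annotation tool.

    Coordinates are 1-based inclusive (InterProScan convention).  ``evalue``
    is ``None`` when the source row carried a non-numeric score.
    """

    protein_id: str
    source: str
    accession: str
    description: str
    start: int
    end: int
    evalue: float | None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"hit {self.accession} on {self.protein_id}: "
                f"require 1 <= start <= end, got [{self.start}, {self.end}]"
            )
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(f"hit {self.accession}: e-value must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class EmbeddingStore:
    """Fixed-width real vectors keyed by protein id.

    Vectors are held as a single float32 matrix; ``ids`` preserves insertion
    order.  Metadata records the provider name and dimensionality so the
    origin of each store is auditable.
    """

    def __init__(
        self,
        ids: Iterable[str],
        vectors: np.ndarray,
        provider: str = "unknown",
    ) -> None:
        self.ids: list[str] = list(ids)
        vectors = np.asarray(vectors, dtype=np.float32)
        if vectors.ndim != 2:
            raise ValueError("vectors must form a 2-D matrix (n_proteins x dim)")
        if len(self.ids) != vectors.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {vectors.shape[0]} vectors"
            )
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate protein id in store: {dup!r}")
        self.vectors = vectors
        self.provider = provider
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    @property
    def dimensionality(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def get(self, protein_id: str) -> np.ndarray:
        try:
            return self.vectors[self._index[protein_id]]
        except KeyError:
            raise KeyError(f"no embedding stored for protein {protein_id!r}") from None

    def matrix(self, ids: Iterable[str]) -> np.ndarray:
        """Rows for the requested ids, in the requested order."""
        rows = []
        for pid in ids:
            if pid not in self._index:
                raise KeyError(f"no embedding stored for protein {pid!r}")
            rows.append(self._index[pid])
        return self.vectors[rows]

    def subset(self, ids: Iterable[str]) -> "EmbeddingStore":
        ids = list(ids)
        return EmbeddingStore(ids, self.matrix(ids), provider=self.provider)

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, np.ndarray], provider: str = "unknown"
    ) -> "EmbeddingStore":
        ids = list(mapping)
        dims = {np.asarray(mapping[i]).shape for i in ids}
        if len(dims) > 1:
            raise ValueError(f"mixed embedding dimensionalities: {sorted(dims)}")
        matrix = np.stack([np.asarray(mapping[i], dtype=np.float32) for i in ids])
        return cls(ids, matrix, provider=provider)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into protein records, preserving order.

    Raises ``ValueError`` naming the id on duplicates; an empty file yields
    an empty list with a warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id in {path.name}: {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(rec.id, str(rec.seq).strip(), desc))
    if not records:
        warnings.warn(f"FASTA file {path} contains no records", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# MMseqs2 cluster TSV


def read_cluster_tsv(path: str | Path, level: str = "standard") -> ClusterAssignment:
    """Read an MMseqs2 ``createtsv`` two-column file (representative, member).

    Every representative is made to map to itself.  A member listed under two
    different representatives is a hard error: silent misparsing of cluster
    files would corrupt the train/test leakage guarantee downstream.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path.name}:{lineno}: expected two tab-separated columns "
                    f"(representative, member), got {line!r}"
                )
            rep, member = parts
            for m, c in ((member, rep), (rep, rep)):
                if m in mapping and mapping[m] != c:
                    raise ValueError(
                        f"{path.name}:{lineno}: protein {m!r} assigned to two "
                        f"clusters ({mapping[m]!r} and {c!r})"
                    )
                mapping[m] = c
    if not mapping:
        warnings.warn(f"cluster file {path} is empty", stacklevel=2)
    return ClusterAssignment(mapping, level=level)


# ---------------------------------------------------------------------------
# InterProScan TSV

_IPR_MIN_COLUMNS = 11


def read_interproscan_tsv(path: str | Path) -> list[DomainHit]:
    """Parse the standard InterProScan tabular output.

    Columns used: protein id (1), analysis (4), signature accession (5),
    signature description (6), start (7), stop (8), score (9).  Rows whose
    score column is non-numeric (e.g. ``-``) yield a hit with missing
    e-value and are retained; e-value filtering happens downstream.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < _IPR_MIN_COLUMNS:
                raise ValueError(
                    f"{path.name}:{lineno}: InterProScan rows need at least "
                    f"{_IPR_MIN_COLUMNS} tab-separated columns, got {len(row)}"
                )
            try:
                evalue: float | None = float(row[8])
            except ValueError:
                evalue = None
            hits.append(
                DomainHit(
                    protein_id=row[0],
                    source=row[3],
                    accession=row[4],
                    description=row[5],
                    start=int(row[6]),
                    end=int(row[7]),
                    evalue=evalue,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Embedding store HDF5 container

_STORE_FORMAT_VERSION = 1


def write_embedding_store(store: EmbeddingStore, path: str | Path) -> None:
    """Write a store to an HDF5 container (float32, lossless round-trip)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = _STORE_FORMAT_VERSION
        fh.attrs["provider"] = store.provider
        fh.attrs["dimensionality"] = store.dimensionality
        fh.create_dataset(
            "ids", data=np.array(store.ids, dtype=h5py.string_dtype("utf-8"))
        )
        fh.create_dataset("vectors", data=store.vectors, dtype="float32")


def read_embedding_store(path: str | Path) -> EmbeddingStore:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"embedding store not found: {path}")
    with h5py.File(path, "r") as fh:
        ids = [i.decode() if isinstance(i, bytes) else str(i) for i in fh["ids"][()]]
        vectors = fh["vectors"][()]
        provider = str(fh.attrs.get("provider", "unknown"))
    return EmbeddingStore(ids, vectors, provider=provider)


# ---------------------------------------------------------------------------
# Predictions TSV

PREDICTION_COLUMNS = [
    "protein_id",
    "lysin_score",
    "is_lysin",
    "subtype_score",
    "subtype",
    "cluster_id",
    "provenance",
]


def write_predictions_tsv(records: Iterable, path: str | Path) -> None:
    """Write prediction records as a TSV with header.

    Scores are serialized with 8 significant digits so a re-read agrees
    within 1e-6.  Missing subtype scores and cluster ids are written as
    empty fields.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PREDICTION_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.protein_id,
                    f"{rec.lysin_score:.8g}",
                    str(rec.is_lysin).lower(),
                    "" if rec.subtype_score is None else f"{rec.subtype_score:.8g}",
                    rec.subtype,
                    rec.cluster_id or "",
                    rec.provenance,
                ]
            )


def read_predictions_tsv(path: str | Path) -> list[dict]:
    """Read back a predictions TSV into plain dicts (scores as floats)."""
    out: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                {
                    "protein_id": row["protein_id"],
                    "lysin_score": float(row["lysin_score"]),
                    "is_lysin": row["is_lysin"] == "true",
                    "subtype_score": (
                        float(row["subtype_score"]) if row["subtype_score"] else None
                    ),
                    "subtype": row["subtype"],
                    "cluster_id": row["cluster_id"] or None,
                    "provenance": row["provenance"],
                }
            )
    return out
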