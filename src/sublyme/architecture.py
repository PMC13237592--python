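"""Domain-level validation and characterization of predicted lysins.

Structure-derived domain segments are mapped onto functional categories —
enzymatically active domain (EAD), cell wall-binding domain (CBD),
miscellaneous, or unknown — using Pfam hits filtered at E-value < 0.001 and
a curated accession -> category dictionary.  From the labelled segments the
module derives per-protein architecture strings ("EAD-CBD"), modularity
histograms, N-/C-terminal positional statistics for bimodular proteins,
domain-occurrence tables split by globular/modular context, a strict
pLDDT > 70 structure-confidence filter, and basic physicochemical
properties (molecular weight, GRAVY).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from sublyme.io_formats import DomainHit, ProteinRecord

__all__ = [
    "EAD", "CBD", "MISC", "UNKNOWN",
    "DomainSegment",
    "DomainDictionary",
    "ArchitectureProfile",
    "PhyschemRecord",
    "default_domain_dictionary",
    "read_domain_dictionary",
    "read_segments_tsv",
    "assign_segment_categories",
    "architecture_string",
    "modularity_histogram",
    "positional_stats",
    "domain_frequency_table",
    "filter_by_confidence",
    "physchem",
]

EAD = "EAD"
CBD = "CBD"
MISC = "MISC"
UNKNOWN = "UNKNOWN"
CATEGORIES = (EAD, CBD, MISC, UNKNOWN)

DEFAULT_EVALUE_THRESHOLD = 1e-3
DEFAULT_PLDDT_CUTOFF = 70.0

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

HISTOGRAM_BINS = ("1", "2", "3", "4", ">=5")


@dataclass(frozen=True)
class DomainSegment:
    """One structure-derived domain segment, 1-based inclusive coordinates.

    ``category`` is one of EAD/CBD/MISC/UNKNOWN once assigned; fresh
    segments from a segmentation table start UNKNOWN.  ``best_accession``
    and ``best_evalue`` record the hit that decided the category (also kept
    for dictionary-absent hits, so unknown-with-hit segments are auditable).
    """

    protein_id: str
    index: int
    start: int
    end: int
    category: str = UNKNOWN
    best_accession: str | None = None
    best_evalue: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"segment {self.index} of {self.protein_id}: require "
                f"1 <= start <= end, got [{self.start}, {self.end}]"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    def contains(self, position: float) -> bool:
        return self.start <= position <= self.end


@dataclass
class DomainDictionary:
    """Signature accession -> (category, human-readable name)."""

    categories: dict[str, str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {a: c for a, c in self.categories.items() if c not in (EAD, CBD, MISC)}
        if bad:
            raise ValueError(f"invalid categories in dictionary: {bad}")

    def __contains__(self, accession: str) -> bool:
        return accession in self.categories

    def category_of(self, accession: str) -> str:
        return self.categories[accession]


@dataclass(frozen=True)
class ArchitectureProfile:
    """Ordered N->C category string and modularity for one protein."""

    protein_id: str
    categories: tuple[str, ...]
    has_lysin_domain: bool
    all_unknown: bool

    @property
    def architecture(self) -> str:
        return "-".join(self.categories)

    @property
    def modularity(self) -> int:
        return len(self.categories)

    @property
    def is_globular(self) -> bool:
        return self.modularity == 1


@dataclass(frozen=True)
class PhyschemRecord:
    """Basic physicochemical panel for one protein."""

    protein_id: str
    molecular_weight: float  # Da, average isotopic masses
    gravy: float  # Kyte-Doolittle mean hydropathy
    length: int


def default_domain_dictionary() -> DomainDictionary:
    """The packaged lysin-domain dictionary (Pfam accession -> EAD/CBD/MISC).

    Seeded from well-described peptidoglycan-hydrolase and wall-binding
    families (Ami2, SLT, GH_108, the PET_M15 group, glucosaminidase,
    lysozymes, PG-binding and SH3-family CBDs); user-extendable and not
    authoritative for production analyses.
    """
    text = (
        resources.files("sublyme").joinpath("data/domain_dictionary.tsv").read_text()
    )
    return _parse_dictionary(text.splitlines())


def read_domain_dictionary(path: str | Path) -> DomainDictionary:
    """TSV with columns accession, category (EAD|CBD|MISC), name."""
    return _parse_dictionary(Path(path).read_text().splitlines())


def _parse_dictionary(lines: Iterable[str]) -> DomainDictionary:
    categories: dict[str, str] = {}
    names: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"dictionary line {lineno}: need accession<TAB>category")
        acc, cat = parts[0], parts[1]
        if acc in categories and categories[acc] != cat:
            raise ValueError(f"accession {acc} mapped to two categories")
        categories[acc] = cat
        if len(parts) > 2:
            names[acc] = parts[2]
    return DomainDictionary(categories=categories, names=names)


def read_segments_tsv(path: str | Path) -> list[DomainSegment]:
    """Segment table: protein id, start, end (1-based inclusive), one row
    per segment; per-protein index follows N->C order of starts."""
    rows: dict[str, list[tuple[int, int]]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ValueError(
                    f"line {lineno}: segment rows need id, start, end"
                )
            rows.setdefault(row[0], []).append((int(row[1]), int(row[2])))
    segments: list[DomainSegment] = []
    for pid, spans in rows.items():
        spans.sort()
        for i, (start, end) in enumerate(spans, start=1):
            segments.append(DomainSegment(pid, i, start, end))
    return segments


def _ordered_segments(segments: Sequence[DomainSegment]) -> list[DomainSegment]:
    ordered = sorted(segments, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"segments of {a.protein_id} overlap: "
                f"[{a.start},{a.end}] and [{b.start},{b.end}]"
            )
    return ordered


def assign_segment_categories(
    segments: Sequence[DomainSegment],
    hits: Sequence[DomainHit],
    dictionary: DomainDictionary | None = None,
    e_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> list[DomainSegment]:
    """Label every segment with a functional category from its Pfam hits.

    Hits with missing e-value or e-value >= threshold (strict <) are
    discarded.  Each surviving hit is attributed to the segment containing
    the midpoint of the hit interval; a hit whose midpoint falls in no
    segment is recorded as unassigned with a warning.  Each segment takes
    the category of its lowest-e-value attributed hit whose accession is in
    the dictionary (ties: longer hit, then lexicographic accession); if its
    only hits are dictionary-absent the segment stays UNKNOWN but records
    the best hit; hit-free segments are UNKNOWN.
    """
    if dictionary is None:
        dictionary = default_domain_dictionary()
    by_protein: dict[str, list[DomainSegment]] = {}
    for seg in segments:
        by_protein.setdefault(seg.protein_id, []).append(seg)
    for pid in by_protein:
        by_protein[pid] = _ordered_segments(by_protein[pid])

    attributed: dict[tuple[str, int], list[DomainHit]] = {}
    for hit in hits:
        if hit.evalue is None or not (hit.evalue < e_threshold):
            continue
        prot_segments = by_protein.get(hit.protein_id, [])
        target = next(
            (s for s in prot_segments if s.contains(hit.midpoint)), None
        )
        if target is None:
            warnings.warn(
                f"hit {hit.accession} on {hit.protein_id} "
                f"(midpoint {hit.midpoint:g}) falls in no segment; unassigned",
                stacklevel=2,
            )
            continue
        attributed.setdefault((hit.protein_id, target.index), []).append(hit)

    labelled: list[DomainSegment] = []
    for pid, prot_segments in by_protein.items():
        for seg in prot_segments:
            seg_hits = attributed.get((pid, seg.index), [])
            if not seg_hits:
                labelled.append(seg)
                continue
            # deterministic precedence: lowest e-value, longest, accession
            seg_hits.sort(key=lambda h: (h.evalue, -h.length, h.accession))
            in_dict = [h for h in seg_hits if h.accession in dictionary]
            if in_dict:
                best = in_dict[0]
                labelled.append(
                    replace(
                        seg,
                        category=dictionary.category_of(best.accession),
                        best_accession=best.accession,
                        best_evalue=best.evalue,
                    )
                )
            else:
                best = seg_hits[0]  # unknown-with-hit: category stays UNKNOWN
                labelled.append(
                    replace(
                        seg,
                        category=UNKNOWN,
                        best_accession=best.accession,
                        best_evalue=best.evalue,
                    )
                )
    return labelled


def architecture_string(segments: Sequence[DomainSegment]) -> ArchitectureProfile:
    """Build the ordered N->C architecture profile of one protein."""
    if not segments:
        raise ValueError("a profile requires at least one segment")
    pids = {s.protein_id for s in segments}
    if len(pids) != 1:
        raise ValueError(f"segments belong to several proteins: {sorted(pids)}")
    ordered = _ordered_segments(segments)
    cats = tuple(s.category for s in ordered)
    return ArchitectureProfile(
        protein_id=ordered[0].protein_id,
        categories=cats,
        has_lysin_domain=any(c in (EAD, CBD) for c in cats),
        all_unknown=all(c == UNKNOWN for c in cats),
    )


def modularity_histogram(
    profiles: Iterable[ArchitectureProfile],
) -> dict[str, int]:
    """Counts of proteins with 1, 2, 3, 4, or >=5 predicted domains."""
    bins = {b: 0 for b in HISTOGRAM_BINS}
    for prof in profiles:
        m = prof.modularity
        bins[str(m) if m < 5 else ">=5"] += 1
    return bins


def positional_stats(
    profiles: Iterable[ArchitectureProfile],
) -> dict[str, float]:
    """N-/C-terminal category fractions over bimodular proteins.

    Fractions of bimodular proteins whose first (N-terminal) or second
    (C-terminal) domain is an EAD or a CBD.  The four fractions need not
    sum to 1 because UNKNOWN and MISC domains exist.
    """
    bimodular = [p for p in profiles if p.modularity == 2]
    if not bimodular:
        raise ValueError("empty stratum: no bimodular profiles supplied")
    n = len(bimodular)
    return {
        "ead_nterm": sum(p.categories[0] == EAD for p in bimodular) / n,
        "ead_cterm": sum(p.categories[1] == EAD for p in bimodular) / n,
        "cbd_nterm": sum(p.categories[0] == CBD for p in bimodular) / n,
        "cbd_cterm": sum(p.categories[1] == CBD for p in bimodular) / n,
        "n_bimodular": n,
    }


def domain_frequency_table(
    segments: Sequence[DomainSegment],
    profiles: Iterable[ArchitectureProfile],
) -> dict[tuple[str, str], int]:
    """Per-accession occurrence counts split by globular/modular context.

    One occurrence per labelled segment with a recorded accession; repeated
    copies of a domain within one protein each count.  Context comes from
    the owning profile: "globular" for single-domain proteins, "modular"
    otherwise.
    """
    modularity = {p.protein_id: p.modularity for p in profiles}
    counts: dict[tuple[str, str], int] = {}
    for seg in segments:
        if seg.best_accession is None:
            continue
        if seg.protein_id not in modularity:
            raise KeyError(f"no profile supplied for protein {seg.protein_id!r}")
        context = "globular" if modularity[seg.protein_id] == 1 else "modular"
        key = (seg.best_accession, context)
        counts[key] = counts.get(key, 0) + 1
    return counts


def filter_by_confidence(
    structure_scores: Mapping[str, float], cutoff: float = DEFAULT_PLDDT_CUTOFF
) -> set[str]:
    """Retain proteins whose mean pLDDT strictly exceeds the cutoff.

    A structure at exactly the cutoff is removed.
    """
    return {pid for pid, score in structure_scores.items() if score > cutoff}


def physchem(record: ProteinRecord) -> PhyschemRecord:
    """Molecular weight (average masses) and Kyte-Doolittle GRAVY.

    Only the 20 canonical residues are accepted; ambiguous letters raise an
    error listing the offending positions (1-based).
    """
    bad_positions = [
        i for i, aa in enumerate(record.sequence, start=1)
        if aa not in CANONICAL_RESIDUES
    ]
    if bad_positions:
        raise ValueError(
            f"protein {record.id!r} has non-canonical residues at positions "
            f"{bad_positions[:10]}"
        )
    analysis = ProteinAnalysis(record.sequence)
    return PhyschemRecord(
        protein_id=record.id,
        molecular_weight=analysis.molecular_weight(),
        gravy=analysis.gravy(),
        length=len(record.sequence),
    )
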