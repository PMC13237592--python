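"""Download-free synthetic inputs with the statistical structure the
pipeline assumes.

The embedding generator draws a two-level hierarchical Gaussian: each class
has a mean, each homology cluster a center scattered around its class mean
(between-cluster spread), and each member protein a vector scattered around
its cluster center (within-cluster spread).  This reproduces the one
property the evaluation protocol depends on — members of a cluster are more
similar to each other than to other clusters — without attempting to mimic
real protein-language-model geometry.  Positive-class members additionally
carry endolysin/VAL subtype labels via an analogous offset, so the same
draw feeds both cascade stages.

Companion generators emit annotation tables and segment/hit fixtures with
known ground truth for the dataset-filter and architecture modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from sublyme.architecture import (
    CBD,
    EAD,
    UNKNOWN,
    ArchitectureProfile,
    DomainSegment,
)
from sublyme.dataset_builder import AnnotationTable, LabelledDataset
from sublyme.io_formats import ClusterAssignment, DomainHit, EmbeddingStore

__all__ = [
    "SimulationParams",
    "SyntheticDataset",
    "simulate_embedding_dataset",
    "permute_labels",
    "simulate_annotation_table",
    "simulate_segments_and_hits",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the hierarchical Gaussian embedding generator.

    Defaults give the separable desk-scale benchmark: 32 dimensions, 40
    clusters per class with 25 members each (2000 vectors, 80 clusters),
    within-cluster spread 0.5, between-cluster spread 1.0, class separation
    4.0 and subtype separation 4.0.
    """

    dimensionality: int = 32
    clusters_per_class: int = 40
    members_per_cluster: int = 25
    sigma_between: float = 1.0
    sigma_within: float = 0.5
    class_separation: float = 4.0
    subtype_separation: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimensionality < 2:
            raise ValueError("dimensionality must be >= 2")
        if self.sigma_between <= 0 or self.sigma_within <= 0:
            raise ValueError("spreads must be > 0")
        if self.class_separation < 0 or self.subtype_separation < 0:
            raise ValueError("separations must be >= 0")
        if self.clusters_per_class < 1 or self.members_per_cluster < 1:
            raise ValueError("need at least one cluster and one member")


@dataclass
class SyntheticDataset:
    """A simulated draw, packaged for both cascade stages.

    ``task1`` labels lysin=1 vs non-lysin=0 over all proteins; ``task2``
    covers only the positives with endolysin=1 vs VAL=0.
    """

    task1: LabelledDataset
    task2: LabelledDataset
    assignment: ClusterAssignment
    params: SimulationParams


def simulate_embedding_dataset(params: SimulationParams) -> SyntheticDataset:
    """Draw a clustered two-class (and two-subtype) embedding dataset.

    Class means sit ``class_separation`` apart along the first axis; within
    the positive class, the two subtypes are offset by
    ``subtype_separation`` along the second axis.  Cluster centers ~
    Normal(class mean, sigma_between^2 I); members ~ Normal(center,
    sigma_within^2 I).  Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    d = params.dimensionality
    half = params.class_separation / 2.0
    class_means = {0: np.zeros(d), 1: np.zeros(d)}
    class_means[0][0] = -half
    class_means[1][0] = +half
    sub_half = params.subtype_separation / 2.0

    ids: list[str] = []
    vectors: list[np.ndarray] = []
    labels: dict[str, int] = {}
    subtype_labels: dict[str, int] = {}
    member_to_cluster: dict[str, str] = {}

    for label in (0, 1):
        for c in range(params.clusters_per_class):
            cluster_id = f"c{label}_{c:03d}"
            center = class_means[label] + params.sigma_between * rng.standard_normal(d)
            # alternate subtypes across positive clusters; subtype is a
            # cluster-level property, as in real homology groups
            subtype = c % 2 if label == 1 else None
            if subtype is not None:
                center = center.copy()
                center[1] += sub_half if subtype == 1 else -sub_half
            for m in range(params.members_per_cluster):
                pid = f"{cluster_id}_m{m:03d}"
                vec = center + params.sigma_within * rng.standard_normal(d)
                ids.append(pid)
                vectors.append(vec.astype(np.float32))
                labels[pid] = label
                member_to_cluster[pid] = cluster_id
                if subtype is not None:
                    subtype_labels[pid] = subtype

    store = EmbeddingStore(ids, np.stack(vectors), provider="synthetic-hierarchical")
    assignment = ClusterAssignment(member_to_cluster, level="standard")
    task1 = LabelledDataset(store, labels, dict(member_to_cluster))
    pos_ids = [i for i in ids if labels[i] == 1]
    task2 = LabelledDataset(
        store.subset(pos_ids),
        {i: subtype_labels[i] for i in pos_ids},
        {i: member_to_cluster[i] for i in pos_ids},
    )
    return SyntheticDataset(task1=task1, task2=task2, assignment=assignment, params=params)


def permute_labels(dataset: LabelledDataset, seed: int) -> LabelledDataset:
    """Return the dataset with labels randomly permuted at cluster level.

    Each cluster keeps one coherent label (as real homology groups would)
    but the cluster -> label map is shuffled, destroying any signal while
    preserving the grouping structure used by the CV harness.
    """
    rng = np.random.default_rng(seed)
    clusters = sorted(set(dataset.clusters.values()))
    cluster_label = {
        c: dataset.labels[
            next(i for i in dataset.ids if dataset.clusters[i] == c)
        ]
        for c in clusters
    }
    values = np.array([cluster_label[c] for c in clusters])
    rng.shuffle(values)
    permuted_cluster_label = dict(zip(clusters, values.tolist()))
    new_labels = {i: permuted_cluster_label[dataset.clusters[i]] for i in dataset.ids}
    return LabelledDataset(dataset.store, new_labels, dict(dataset.clusters))


# ---------------------------------------------------------------------------
# Annotation-table fixture

_UNRELATED_TERMS = [
    "terminase large subunit",
    "major capsid protein",
    "tail fiber protein",
    "portal protein",
    "DNA polymerase",
    "helicase",
]


def simulate_annotation_table(
    seed: int, n_per_kind: int = 2, exclusion_terms: Iterable[str] | None = None
) -> tuple[AnnotationTable, set[str]]:
    """Annotation table with known filter ground truth.

    Emits ``n_per_kind`` proteins of each kind: (a) unannotated, (b)
    annotated with a lysin-related term from the exclusion list, (c)
    annotated with an unrelated structural/replication term.  Returns the
    table together with the set of ids a correct exclusion filter retains
    (exactly the unrelated kind).
    """
    from sublyme.dataset_builder import default_exclusion_terms

    terms = list(exclusion_terms) if exclusion_terms is not None else default_exclusion_terms()
    rng = np.random.default_rng(seed)
    table: dict[str, set[str]] = {}
    retained: set[str] = set()
    for i in range(n_per_kind):
        table[f"noann_{i}"] = set()
        lys = terms[rng.integers(len(terms))]
        table[f"lysrel_{i}"] = {f"putative {lys} protein"}
        unrel = _UNRELATED_TERMS[rng.integers(len(_UNRELATED_TERMS))]
        table[f"unrel_{i}"] = {unrel}
        retained.add(f"unrel_{i}")
    return AnnotationTable(table), retained


# ---------------------------------------------------------------------------
# Segment / hit fixture


def _hexamodular_fixture() -> tuple[list[DomainSegment], list[DomainHit], ArchitectureProfile]:
    """A six-domain endolysin modeled on known hexamodular architectures:
    three EADs (PET_M15, a lysozyme, Ami2), one SH3-family CBD, and two
    segments with no annotation."""
    pid = "hexa_1G20T"
    bounds = [(1, 90), (95, 210), (215, 330), (335, 400), (405, 470), (475, 540)]
    segments = [
        DomainSegment(pid, i + 1, s, e) for i, (s, e) in enumerate(bounds)
    ]
    hits = [
        DomainHit(pid, "Pfam", "PF02557", "PET_M15", 5, 85, 1e-25),
        DomainHit(pid, "Pfam", "PF13702", "Lysozyme 2", 100, 205, 3e-18),
        DomainHit(pid, "Pfam", "PF01510", "Ami2", 220, 325, 2e-30),
        DomainHit(pid, "Pfam", "PF08460", "SH3_5", 340, 395, 4e-12),
    ]
    expected = ArchitectureProfile(
        protein_id=pid,
        categories=(EAD, EAD, EAD, CBD, UNKNOWN, UNKNOWN),
        has_lysin_domain=True,
        all_unknown=False,
    )
    return segments, hits, expected


def simulate_segments_and_hits(
    seed: int,
) -> tuple[list[DomainSegment], list[DomainHit], dict[str, ArchitectureProfile]]:
    """Segment table + hits + expected profiles for the architecture module.

    Always includes: the hexamodular worked example; a bimodular EAD-CBD
    protein whose CBD (PG1) appears in two copies in a companion trimodular
    protein; a protein whose only hit sits at e-value 0.01 and must be
    discarded at the 0.001 cutoff (all-unknown result); and a globular
    single-EAD protein.  Deterministic per seed (the seed perturbs segment
    bounds, never the ground truth).
    """
    rng = np.random.default_rng(seed)
    segments: list[DomainSegment] = []
    hits: list[DomainHit] = []
    expected: dict[str, ArchitectureProfile] = {}

    hexa_segments, hexa_hits, hexa_profile = _hexamodular_fixture()
    segments += hexa_segments
    hits += hexa_hits
    expected[hexa_profile.protein_id] = hexa_profile

    jitter = int(rng.integers(0, 10))

    pid = "bimod_ead_cbd"
    segments += [
        DomainSegment(pid, 1, 1, 160 + jitter),
        DomainSegment(pid, 2, 165 + jitter, 240 + jitter),
    ]
    hits += [
        DomainHit(pid, "Pfam", "PF01464", "SLT", 10, 150, 1e-20),
        DomainHit(pid, "Pfam", "PF01471", "PG1", 170 + jitter, 235 + jitter, 5e-10),
    ]
    expected[pid] = ArchitectureProfile(pid, (EAD, CBD), True, False)

    pid = "trimod_double_pg1"
    segments += [
        DomainSegment(pid, 1, 1, 120),
        DomainSegment(pid, 2, 125, 190),
        DomainSegment(pid, 3, 195, 260),
    ]
    hits += [
        DomainHit(pid, "Pfam", "PF05838", "GH_108", 5, 115, 2e-22),
        DomainHit(pid, "Pfam", "PF01471", "PG1", 130, 185, 1e-9),
        DomainHit(pid, "Pfam", "PF01471", "PG1", 200, 255, 3e-8),
    ]
    expected[pid] = ArchitectureProfile(pid, (EAD, CBD, CBD), True, False)

    pid = "weak_hit_only"
    segments += [DomainSegment(pid, 1, 1, 140)]
    hits += [DomainHit(pid, "Pfam", "PF01510", "Ami2", 10, 130, 1e-2)]
    expected[pid] = ArchitectureProfile(pid, (UNKNOWN,), False, True)

    pid = "globular_slt"
    segments += [DomainSegment(pid, 1, 1, 150)]
    hits += [DomainHit(pid, "Pfam", "PF01464", "SLT", 8, 145, 1e-15)]
    expected[pid] = ArchitectureProfile(pid, (EAD,), True, False)

    return segments, hits, expected
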