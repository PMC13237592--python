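"""The two-stage lysin classifier cascade.

Stage 1 separates lysins from non-lysins; stage 2 classifies predicted
lysins as endolysins or virion-associated lysins (VALs).  Both stages are
RBF-kernel support vector machines at library-default hyperparameters
(C = 1.0, gamma = "scale") with Platt-scaled probability outputs.  The
decision rule is strict: a protein is called a lysin only when its score
exceeds the threshold (default 50%), never at equality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import joblib
import numpy as np
from sklearn.svm import SVC

from sublyme.dataset_builder import LabelledDataset
from sublyme.io_formats import ClusterAssignment, EmbeddingStore

__all__ = [
    "ProbabilisticBinaryClassifier",
    "TrainedCascade",
    "PredictionRecord",
    "fit_stage",
    "train_final_cascade",
    "predict_cascade",
    "propagate_to_members",
    "save_cascade",
    "load_cascade",
]

BUNDLE_FORMAT_VERSION = 1

ENDOLYSIN = "endolysin"
VAL = "VAL"
NO_SUBTYPE = "none"


@dataclass
class ProbabilisticBinaryClassifier:
    """A fitted RBF-SVM with Platt-scaled probabilities for the positive class."""

    model: SVC
    dimensionality: int
    positive_label: str = "positive"

    def score(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each row of X."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.dimensionality:
            raise ValueError(
                f"embedding dimensionality {X.shape[1]} does not match the "
                f"classifier's training dimensionality {self.dimensionality}"
            )
        pos_col = list(self.model.classes_).index(1)
        return self.model.predict_proba(X)[:, pos_col]


@dataclass(frozen=True)
class PredictionRecord:
    """Cascade output for one protein (or one cluster consensus)."""

    protein_id: str
    lysin_score: float
    is_lysin: bool
    subtype_score: float | None
    subtype: str
    cluster_id: str | None = None
    provenance: str = "direct"

    def __post_init__(self) -> None:
        if (self.subtype == NO_SUBTYPE) != (not self.is_lysin):
            raise ValueError(
                f"{self.protein_id}: subtype must be {NO_SUBTYPE!r} exactly "
                f"when is_lysin is false"
            )
        if (self.subtype_score is not None) != self.is_lysin:
            raise ValueError(
                f"{self.protein_id}: subtype_score must be present exactly "
                f"when is_lysin is true"
            )


@dataclass
class TrainedCascade:
    """Two fitted stages plus decision thresholds and provenance metadata."""

    stage1: ProbabilisticBinaryClassifier
    stage2: ProbabilisticBinaryClassifier
    threshold1: float = 0.5
    threshold2: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, t in (("threshold1", self.threshold1), ("threshold2", self.threshold2)):
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {t}")


def fit_stage(dataset: LabelledDataset, seed: int) -> ProbabilisticBinaryClassifier:
    """Fit one RBF-SVM stage at default hyperparameters.

    C = 1.0 and the "scale" kernel-width heuristic
    (gamma = 1 / (n_features * Var(X))); probabilities via Platt-style
    sigmoid calibration fitted by internal cross-validation, seeded for
    reproducibility.
    """
    y = dataset.y()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"dataset contains a single class ({classes.tolist()}); both "
            f"classes are required to fit a stage"
        )
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 examples")
    X = dataset.X().astype(np.float64)
    model = SVC(
        kernel="rbf", C=1.0, gamma="scale", probability=True, random_state=seed
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        # sklearn 1.9 deprecates probability=True in favour of an explicit
        # calibration wrapper; the internal Platt fit is what we want here.
        _warnings.filterwarnings("ignore", category=FutureWarning)
        model.fit(X, y)
    return ProbabilisticBinaryClassifier(model=model, dimensionality=X.shape[1])


def train_final_cascade(
    task1: LabelledDataset, task2: LabelledDataset, seed: int
) -> TrainedCascade:
    """Train both final stages on all supplied labelled data.

    Task-2 labels (endolysin=1, VAL=0) exist only for lysins, so task2 ids
    must be a subset of task1's positive ids.
    """
    task1_positives = {i for i in task1.ids if task1.labels[i] == 1}
    stray = set(task2.ids) - task1_positives
    if stray:
        raise ValueError(
            f"task-2 ids must be task-1 positives; offending ids: "
            f"{sorted(stray)[:5]}"
        )
    stage1 = fit_stage(task1, seed)
    stage2 = fit_stage(task2, seed)
    stage1.positive_label = "lysin"
    stage2.positive_label = ENDOLYSIN
    metadata = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "task1_size": len(task1),
        "task2_size": len(task2),
        "seed": seed,
        "stage2_positive_class": ENDOLYSIN,
        "trained_at": datetime.now(timezone.utc).isoformat(),
    }
    return TrainedCascade(stage1=stage1, stage2=stage2, metadata=metadata)


def predict_cascade(
    cascade: TrainedCascade,
    store: EmbeddingStore,
    threshold1: float | None = None,
    threshold2: float | None = None,
    clusters: Mapping[str, str] | None = None,
) -> list[PredictionRecord]:
    """Apply both stages consecutively with strict-> thresholding.

    is_lysin = (lysin_score > threshold1); stage 2 is evaluated only for
    predicted lysins, with subtype = endolysin when subtype_score >
    threshold2, else VAL.  A score exactly at the threshold is negative.
    """
    t1 = cascade.threshold1 if threshold1 is None else threshold1
    t2 = cascade.threshold2 if threshold2 is None else threshold2
    for name, t in (("threshold1", t1), ("threshold2", t2)):
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {t}")
    if len(store) == 0:
        return []
    if store.dimensionality != cascade.stage1.dimensionality:
        raise ValueError(
            f"store dimensionality {store.dimensionality} does not match "
            f"cascade dimensionality {cascade.stage1.dimensionality}"
        )
    scores1 = cascade.stage1.score(store.vectors)
    lysin_mask = scores1 > t1
    records: list[PredictionRecord] = []
    scores2 = np.full(len(store), np.nan)
    if lysin_mask.any():
        scores2[lysin_mask] = cascade.stage2.score(store.vectors[lysin_mask])
    for i, pid in enumerate(store.ids):
        if lysin_mask[i]:
            s2 = float(scores2[i])
            subtype = ENDOLYSIN if s2 > t2 else VAL
            rec = PredictionRecord(
                protein_id=pid,
                lysin_score=float(scores1[i]),
                is_lysin=True,
                subtype_score=s2,
                subtype=subtype,
                cluster_id=clusters.get(pid) if clusters else None,
            )
        else:
            rec = PredictionRecord(
                protein_id=pid,
                lysin_score=float(scores1[i]),
                is_lysin=False,
                subtype_score=None,
                subtype=NO_SUBTYPE,
                cluster_id=clusters.get(pid) if clusters else None,
            )
        records.append(rec)
    return records


def propagate_to_members(
    cluster_predictions: Iterable[PredictionRecord],
    assignment: ClusterAssignment,
) -> list[PredictionRecord]:
    """Extend cluster-consensus predictions to every cluster member.

    Each member of a lysin-positive cluster receives a copy of the cluster's
    record (same scores, provenance "propagated"); members of negative
    clusters are omitted.  Output size equals the summed sizes of positive
    clusters.
    """
    clusters = assignment.clusters()
    out: list[PredictionRecord] = []
    for rec in cluster_predictions:
        cluster_id = rec.cluster_id or rec.protein_id
        if cluster_id not in clusters:
            raise KeyError(
                f"prediction refers to cluster {cluster_id!r} absent from the "
                f"assignment"
            )
        if not rec.is_lysin:
            continue
        for member in clusters[cluster_id]:
            out.append(
                PredictionRecord(
                    protein_id=member,
                    lysin_score=rec.lysin_score,
                    is_lysin=True,
                    subtype_score=rec.subtype_score,
                    subtype=rec.subtype,
                    cluster_id=cluster_id,
                    provenance="propagated",
                )
            )
    return out


def save_cascade(cascade: TrainedCascade, path: str | Path) -> None:
    """Write a versioned model bundle: two serialized stages + JSON metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(cascade.stage1, path / "stage1.joblib")
    joblib.dump(cascade.stage2, path / "stage2.joblib")
    meta = dict(cascade.metadata)
    meta.update(
        {
            "format_version": BUNDLE_FORMAT_VERSION,
            "threshold1": cascade.threshold1,
            "threshold2": cascade.threshold2,
        }
    )
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_cascade(path: str | Path) -> TrainedCascade:
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no cascade bundle at {path} (metadata.json missing)")
    meta = json.loads(meta_path.read_text())
    version = meta.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {version} is not supported "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    stage1 = joblib.load(path / "stage1.joblib")
    stage2 = joblib.load(path / "stage2.joblib")
    return TrainedCascade(
        stage1=stage1,
        stage2=stage2,
        threshold1=float(meta.get("threshold1", 0.5)),
        threshold2=float(meta.get("threshold2", 0.5)),
        metadata=meta,
    )
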