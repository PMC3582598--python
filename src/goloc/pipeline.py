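"""End-to-end orchestration: key resolution -> GO vectors -> SVM -> labels.

Ties the retrieval, feature and classifier layers into train / predict /
leave-one-out workflows over a :class:`Dataset`.  Leave-one-out
cross-validation iterates over *actual* proteins (each held out once,
whatever its multiplicity); by default the GO subspace is rebuilt from
the remaining proteins in every fold so no term identity leaks from the
held-out protein, with a cheaper frozen-subspace variant available.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotations import (
    MODE_AC,
    MODE_AC_SEQ,
    MODE_SEQ,
    MODES,
    AnnotationTable,
    HomologList,
    ProteinRecord,
    first_annotated_key,
    resolve_keys,
)
from .classifier import (
    KernelSpec,
    MultiLabelSVMModel,
    Prediction,
    decide,
    train,
)
from .evaluation import EvalReport, evaluate
from .features import (
    GOSubspace,
    VECTOR_MODES,
    build_subspace,
    dropped_occurrences,
    fuse,
    make_query_set,
    vectorize,
)

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """Proteins with labels, their GO annotations and homology evidence."""

    proteins: list
    annotations: AnnotationTable
    homologs: dict = field(default_factory=dict)   # protein_id -> HomologList
    class_names: list = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.class_names)

    def true_label_sets(self) -> list:
        return [p.labels for p in self.proteins]

    def get_homologs(self, protein_id: str) -> HomologList:
        return self.homologs.get(protein_id) or HomologList(protein_id)


@dataclass
class PipelineConfig:
    """The experimental knobs of one run.

    ``mode`` selects the input case: ``"ac"`` (accession only, case 1),
    ``"seq"`` (sequence only — homolog accessions, case 2) or
    ``"ac+seq"`` (both, case 3).  ``n_homologs`` is the number of
    homolog keys used in the sequence modes.  ``vector_mode`` picks
    term-frequency or binary GO vectors.  ``rebuild_subspace`` controls
    whether each LOOCV fold rebuilds the GO subspace from its own
    training proteins (default) or a single frozen subspace is reused.
    ``train_fused`` trains on each protein's weight-fused vector instead
    of one instance per accession key.  ``cascade`` walks down the
    homolog ranking until an annotated accession is found (the
    novel-protein procedure).
    """

    mode: str = MODE_AC
    n_homologs: int = 1
    vector_mode: str = "tf"
    kernel: KernelSpec = field(default_factory=KernelSpec)
    C: float = 0.1
    rebuild_subspace: bool = True
    train_fused: bool = False
    cascade: bool = False
    l2_normalize: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.vector_mode not in VECTOR_MODES:
            raise ValueError(f"unknown vector mode {self.vector_mode!r}")
        if self.mode != MODE_AC and self.n_homologs < 1:
            raise ValueError("n_homologs must be >= 1 in sequence modes")

    @property
    def case(self) -> int:
        return {MODE_AC: 1, MODE_SEQ: 2, MODE_AC_SEQ: 3}[self.mode]


def query_keys(protein: ProteinRecord, dataset: Dataset,
               cfg: PipelineConfig) -> list:
    """Accession keys for one protein under the configured input case."""
    if cfg.mode == MODE_AC:
        return resolve_keys(protein, None, MODE_AC)
    homologs = dataset.get_homologs(protein.protein_id)
    if cfg.cascade:
        key = first_annotated_key(homologs, dataset.annotations)
        hom_keys = [key] if key is not None else []
        if cfg.mode == MODE_SEQ:
            return hom_keys
        return [protein.accession] + hom_keys
    return resolve_keys(protein, homologs, cfg.mode, cfg.n_homologs)


def build_training_subspace(dataset: Dataset, cfg: PipelineConfig,
                            exclude: frozenset = frozenset()) -> GOSubspace:
    """GO subspace spanned by the training proteins' resolved keys."""
    multisets = []
    for protein in dataset.proteins:
        if protein.protein_id in exclude:
            continue
        for key in query_keys(protein, dataset, cfg):
            multisets.append(dataset.annotations.terms(key))
    return build_subspace(multisets)


def _training_matrix(dataset: Dataset, cfg: PipelineConfig,
                     subspace: GOSubspace,
                     exclude: frozenset = frozenset()):
    """Training instances and their label sets.

    Default: every resolved accession key of a training protein yields a
    separate instance carrying the protein's full label set.  With
    ``train_fused`` each protein contributes its single weight-fused
    vector instead.  A protein with no keys at all (sequence mode, no
    homologs) contributes one zero vector.
    """
    rows, label_sets = [], []
    for protein in dataset.proteins:
        if protein.protein_id in exclude:
            continue
        keys = query_keys(protein, dataset, cfg)
        if cfg.train_fused:
            qs = make_query_set(keys, dataset.annotations, subspace,
                                cfg.vector_mode, case=None,
                                l2_normalize=cfg.l2_normalize)
            rows.append(fuse(qs))
            label_sets.append(protein.labels)
        elif not keys:
            rows.append(np.zeros(subspace.T))
            label_sets.append(protein.labels)
        else:
            for key in keys:
                vec = vectorize(dataset.annotations.terms(key), subspace,
                                cfg.vector_mode, cfg.l2_normalize)
                rows.append(vec.values)
                label_sets.append(protein.labels)
    return np.vstack(rows), label_sets


def train_model(dataset: Dataset, cfg: PipelineConfig,
                subspace: GOSubspace | None = None,
                exclude: frozenset = frozenset()):
    """Build the subspace (unless given) and train the multi-label model."""
    if subspace is None:
        subspace = build_training_subspace(dataset, cfg, exclude)
    X, label_sets = _training_matrix(dataset, cfg, subspace, exclude)
    model = train(X, label_sets, dataset.M, cfg.kernel, cfg.C,
                  class_names=list(dataset.class_names))
    logger.info("trained model: M=%d, T=%d, %d training instances",
                dataset.M, subspace.T, X.shape[0])
    return model, subspace


def predict_one(model: MultiLabelSVMModel, subspace: GOSubspace,
                dataset: Dataset, protein: ProteinRecord,
                cfg: PipelineConfig) -> Prediction:
    """Score one query protein and decide its location set."""
    keys = query_keys(protein, dataset, cfg)
    qs = make_query_set(keys, dataset.annotations, subspace,
                        cfg.vector_mode, case=None,
                        l2_normalize=cfg.l2_normalize)
    scores = model.score_query_set(qs)
    labels, fallback = decide(scores)
    return Prediction(protein_id=protein.protein_id, scores=tuple(scores),
                      labels=labels, fallback_used=fallback,
                      zero_vector=qs.is_zero)


def predict_all(model: MultiLabelSVMModel, subspace: GOSubspace,
                dataset: Dataset, cfg: PipelineConfig,
                proteins: Sequence[ProteinRecord] | None = None) -> list:
    """Predict every protein (or the given subset) with one model."""
    proteins = dataset.proteins if proteins is None else proteins
    dropped = 0
    predictions = []
    for protein in proteins:
        for key in query_keys(protein, dataset, cfg):
            dropped += dropped_occurrences(
                dataset.annotations.terms(key), subspace)
        predictions.append(predict_one(model, subspace, dataset, protein, cfg))
    logger.info("predicted %d protein(s); %d out-of-subspace GO occurrence(s) "
                "dropped", len(predictions), dropped)
    return predictions


def loocv(dataset: Dataset, cfg: PipelineConfig) -> tuple:
    """Leave-one-out cross-validation over actual proteins.

    Each of the N proteins is predicted by a model trained on the other
    N - 1.  Returns ``(predictions, EvalReport)``.
    """
    N = len(dataset.proteins)
    if N < 3:
        raise ValueError("leave-one-out needs at least 3 proteins")
    frozen = None
    if not cfg.rebuild_subspace:
        frozen = build_training_subspace(dataset, cfg)
    predictions = []
    for protein in dataset.proteins:
        exclude = frozenset({protein.protein_id})
        model, subspace = train_model(dataset, cfg, subspace=frozen,
                                      exclude=exclude)
        predictions.append(predict_one(model, subspace, dataset, protein, cfg))
    report = evaluate(dataset.true_label_sets(),
                      [p.labels for p in predictions], dataset.M,
                      class_names=list(dataset.class_names))
    return predictions, report


# -- prediction file I/O ---------------------------------------------------

def write_predictions(predictions: Iterable[Prediction],
                      class_names: Sequence[str], path) -> None:
    """Predictions TSV: id, labels, per-class scores, flags."""
    class_names = list(class_names)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        fh.write("#classes\t" + ";".join(class_names) + "\n")
        writer.writerow(["#protein_id", "labels",
                         *[f"score_{i+1}" for i in range(len(class_names))],
                         "fallback", "zero_vector"])
        for p in predictions:
            labels = ";".join(class_names[m - 1] for m in sorted(p.labels))
            writer.writerow([p.protein_id, labels,
                             *[f"{s:.6g}" for s in p.scores],
                             int(p.fallback_used), int(p.zero_vector)])


def load_predictions(path) -> tuple:
    """Read a predictions TSV back as ``([(id, label_set)...], class_names)``."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#classes"):
        raise ValueError("predictions file must start with a '#classes' header")
    class_names = [c.strip() for c in lines[0].split("\t", 1)[1].split(";")]
    index = {name: i + 1 for i, name in enumerate(class_names)}
    rows = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            continue
        parts = ln.split("\t")
        raw = parts[1] if len(parts) > 1 else ""
        if raw == "-":          # unpredictable marker (lookup baseline)
            rows.append((parts[0], None))
            continue
        labels = frozenset(index[t] for t in filter(None, raw.split(";")))
        rows.append((parts[0], labels))
    return rows, class_names
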