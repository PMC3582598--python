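"""Multi-label one-vs-rest SVM classification of GO vectors.

For an M-location problem, M independent soft-margin binary SVMs are
trained, one per location.  A protein residing in several locations is a
single training instance whose transformed label is +1 for every one of
its locations and -1 elsewhere — it is never duplicated across classes,
which would place identical patterns on both sides of a margin.

At prediction time the m-th SVM score of a query with key vectors
q_0..q_n and fusion weights w_j is

    s_m(q) = sum_j w_j [ sum_{r in S_m} alpha_{m,r} y_{m,r} K(p_r, q_j) + b_m ]

(with sum_j w_j = 1 the bias contributes exactly b_m).  The predicted
location set is every class with a strictly positive score; if no score
is positive, the single top-scoring class is emitted instead, so a
prediction is never empty.

The per-class quadratic programs are solved by scikit-learn's SVC; the
fitted duals, support vectors and biases are extracted into this
module's own model object, which evaluates kernels itself so that a
serialized model is self-contained.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.svm import SVC

from .features import QueryVectorSet

logger = logging.getLogger(__name__)

#: Sentinel score of a class whose SVM could not be trained (no positive
#: or no negative examples).  It can never win the positive-score rule
#: and loses every argmax against a real SVM.
STUB_SCORE = float("-inf")

MODEL_FORMAT = "goloc-svm/1"


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    * ``linear``: K(x, y) = <x, y> (the default used throughout).
    * ``rbf``: K(x, y) = exp(-||x - y||^2 / (2 sigma^2)); ``sigma`` is
      the kernel width, conventionally swept over {2^-2, ..., 2^5}.
    * ``polynomial``: K(x, y) = (<x, y> + 1)^d with integer degree
      ``degree`` in {2, 3, ...}.
    """

    family: str = "linear"
    sigma: float | None = None
    degree: int | None = None

    def __post_init__(self):
        if self.family not in ("linear", "rbf", "polynomial"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("rbf kernel requires sigma > 0")
        if self.family == "polynomial":
            if self.degree is None or self.degree < 2:
                raise ValueError("polynomial kernel requires integer degree >= 2")

    def gram(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Kernel matrix K[i, j] = K(X[i], Y[j])."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if self.family == "linear":
            return X @ Y.T
        if self.family == "polynomial":
            return (X @ Y.T + 1.0) ** self.degree
        sq = (
            np.sum(X * X, axis=1)[:, None]
            + np.sum(Y * Y, axis=1)[None, :]
            - 2.0 * (X @ Y.T)
        )
        np.maximum(sq, 0.0, out=sq)
        return np.exp(-sq / (2.0 * self.sigma**2))

    def sklearn_params(self) -> dict:
        """Parameter mapping for :class:`sklearn.svm.SVC`."""
        if self.family == "linear":
            return {"kernel": "linear"}
        if self.family == "rbf":
            return {"kernel": "rbf", "gamma": 1.0 / (2.0 * self.sigma**2)}
        return {"kernel": "poly", "degree": self.degree,
                "gamma": 1.0, "coef0": 1.0}

    def to_dict(self) -> dict:
        d = {"family": self.family}
        if self.sigma is not None:
            d["sigma"] = self.sigma
        if self.degree is not None:
            d["degree"] = self.degree
        if self.family == "rbf":
            d["convention"] = "exp(-||x-y||^2 / (2 sigma^2))"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(family=d["family"], sigma=d.get("sigma"),
                   degree=d.get("degree"))


def transform_labels(labels: Iterable[int], M: int) -> np.ndarray:
    """Transformed +/-1 label vector of a (possibly multi-label) protein.

    Component m is +1 iff location m is in the protein's label set, else
    -1; multi-label proteins therefore carry more than one +1.
    """
    label_set = set(labels)
    if not label_set:
        raise ValueError("label set must be non-empty")
    if not label_set <= set(range(1, M + 1)):
        raise ValueError(f"labels {sorted(label_set)} out of range 1..{M}")
    y = -np.ones(M)
    for m in label_set:
        y[m - 1] = 1.0
    return y


@dataclass
class ClassSVM:
    """One trained binary SVM in dual form (or a stub for an empty class)."""

    bias: float = 0.0
    support_vectors: np.ndarray | None = None   # (n_sv, T)
    alpha: np.ndarray | None = None             # Lagrange multipliers, >= 0
    labels: np.ndarray | None = None            # transformed labels y_r, +/-1
    weights: np.ndarray | None = None           # linear kernel: sum alpha y p_r
    is_stub: bool = False

    def dual_score(self, x: np.ndarray, kernel: KernelSpec) -> float:
        """sum_{r in S} alpha_r y_r K(p_r, x) + b."""
        if self.is_stub:
            return STUB_SCORE
        k = kernel.gram(self.support_vectors, x[None, :])[:, 0]
        return float((self.alpha * self.labels) @ k + self.bias)

    def weight_score(self, x: np.ndarray) -> float:
        """w . x + b (linear kernel only)."""
        if self.is_stub:
            return STUB_SCORE
        if self.weights is None:
            raise ValueError("weight-form score requires a linear kernel")
        return float(self.weights @ x + self.bias)

    def kkt_gap(self) -> float:
        """|sum_r alpha_r y_r| — zero at a KKT point."""
        if self.is_stub:
            return 0.0
        return abs(float((self.alpha * self.labels).sum()))


@dataclass
class MultiLabelSVMModel:
    """M one-vs-rest SVMs over a shared GO subspace."""

    M: int
    n_features: int
    kernel: KernelSpec
    C: float
    class_svms: list[ClassSVM] = field(default_factory=list)
    class_names: list[str] | None = None

    def score_single(self, x: np.ndarray) -> np.ndarray:
        """Per-class scores of one vector (single-key form of the score)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_features,):
            raise ValueError(
                f"query has {x.shape} coordinates, model expects "
                f"({self.n_features},)")
        return np.array([svm.dual_score(x, self.kernel)
                         for svm in self.class_svms])

    def score_query_set(self, qs: QueryVectorSet) -> np.ndarray:
        """Fused per-class scores sum_j w_j s_m(q_j) of a query-vector set."""
        if len(qs.vectors[0]) != self.n_features:
            raise ValueError(
                f"query vectors have length {len(qs.vectors[0])}, model "
                f"expects {self.n_features}")
        scores = np.zeros(self.M)
        for m, svm in enumerate(self.class_svms):
            if svm.is_stub:
                scores[m] = STUB_SCORE
                continue
            scores[m] = sum(
                w * svm.dual_score(v.values, self.kernel)
                for w, v in zip(qs.weights, qs.vectors))
        return scores

    def weight_scores(self, x: np.ndarray) -> np.ndarray:
        """Per-class w.x + b scores (linear kernel cross-check)."""
        return np.array([svm.weight_score(np.asarray(x, dtype=float))
                         for svm in self.class_svms])

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        classes = []
        for svm in self.class_svms:
            if svm.is_stub:
                classes.append({"stub": True})
                continue
            entry = {
                "stub": False,
                "bias": svm.bias,
                "support_vectors": svm.support_vectors.tolist(),
                "alpha": svm.alpha.tolist(),
                "labels": svm.labels.tolist(),
            }
            if svm.weights is not None:
                entry["weights"] = svm.weights.tolist()
            classes.append(entry)
        return {
            "format": MODEL_FORMAT,
            "M": self.M,
            "n_features": self.n_features,
            "kernel": self.kernel.to_dict(),
            "C": self.C,
            "class_names": self.class_names,
            "classes": classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultiLabelSVMModel":
        if d.get("format") != MODEL_FORMAT:
            raise ValueError(f"unsupported model format {d.get('format')!r}")
        kernel = KernelSpec.from_dict(d["kernel"])
        svms = []
        for entry in d["classes"]:
            if entry["stub"]:
                svms.append(ClassSVM(is_stub=True))
                continue
            weights = entry.get("weights")
            svms.append(ClassSVM(
                bias=entry["bias"],
                support_vectors=np.asarray(entry["support_vectors"]),
                alpha=np.asarray(entry["alpha"]),
                labels=np.asarray(entry["labels"]),
                weights=None if weights is None else np.asarray(weights),
            ))
        return cls(M=d["M"], n_features=d["n_features"], kernel=kernel,
                   C=d["C"], class_svms=svms, class_names=d.get("class_names"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "MultiLabelSVMModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train(X: np.ndarray, label_sets: Sequence[Iterable[int]], M: int,
          kernel: KernelSpec | None = None, C: float = 0.1,
          class_names: list[str] | None = None) -> MultiLabelSVMModel:
    """Train M one-vs-rest binary SVMs on GO training vectors.

    Each row of ``X`` is one training instance (a protein's own-accession
    vector, or one of its homolog-key vectors) carrying the protein's
    full label set.  ``C`` is the soft-margin penalty; the default 0.1 is
    used with the linear kernel unless configured otherwise.

    A class with no positive (or no negative) instances gets a stub SVM
    with a constant minus-infinity score: it can never be predicted by
    the positive-score rule, and it only wins the argmax fallback if all
    classes are stubs, in which case training fails outright.
    """
    kernel = kernel or KernelSpec()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(label_sets):
        raise ValueError("X must be (n_instances, T) matching label_sets")
    if M < 2:
        raise ValueError("need at least two classes")
    Y = np.stack([transform_labels(ls, M) for ls in label_sets])
    svms: list[ClassSVM] = []
    for m in range(M):
        y = Y[:, m]
        if (y > 0).all() or (y < 0).all():
            logger.warning(
                "class %d has no %s training instances; using stub",
                m + 1, "negative" if (y > 0).all() else "positive")
            svms.append(ClassSVM(is_stub=True))
            continue
        svc = SVC(C=C, **kernel.sklearn_params())
        svc.fit(X, y)
        # For binary SVC with classes_ == [-1, +1], dual_coef_[0] holds
        # alpha_r * y_r and decision_function is positive for class +1.
        assert list(svc.classes_) == [-1.0, 1.0]
        dual = svc.dual_coef_[0]
        alpha = np.abs(dual)
        y_sv = np.sign(dual)
        sv = svc.support_vectors_.copy()
        weights = None
        if kernel.family == "linear":
            weights = (dual[:, None] * sv).sum(axis=0)
        svms.append(ClassSVM(
            bias=float(svc.intercept_[0]), support_vectors=sv,
            alpha=alpha, labels=y_sv, weights=weights))
    if all(s.is_stub for s in svms):
        raise ValueError("every class lacks positive or negative instances")
    return MultiLabelSVMModel(M=M, n_features=X.shape[1], kernel=kernel,
                              C=C, class_svms=svms, class_names=class_names)


def decide(scores: Sequence[float]) -> tuple[frozenset, bool]:
    """Predicted location set from per-class scores, never empty.

    Every class with a strictly positive score is predicted; if none is
    positive, the number of locations is set to one and the single
    top-scoring class is emitted (ties broken by smallest class index).
    Returns ``(predicted_set, fallback_used)``.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("need scores for at least two classes")
    positive = np.flatnonzero(s > 0)
    if positive.size:
        return frozenset(int(m) + 1 for m in positive), False
    return frozenset({int(np.argmax(s)) + 1}), True


@dataclass(frozen=True)
class Prediction:
    """One query's scores, predicted location set and provenance flags."""

    protein_id: str
    scores: tuple
    labels: frozenset
    fallback_used: bool = False
    zero_vector: bool = False

    def __post_init__(self):
        if not self.labels:
            raise ValueError("predicted set must be non-empty")
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        object.__setattr__(self, "labels", frozenset(self.labels))
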