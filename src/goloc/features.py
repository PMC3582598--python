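"""GO subspace selection and GO-vector construction.

The T distinct GO terms found across the training proteins span a
T-dimensional Euclidean space.  Each protein becomes a point in that
space, with coordinates either binary ("GO hit": the term appears at
least once in the search result for the protein's accession keys) or
term-frequency (the number of occurrences of the term, preserving the
fact that a term may annotate the same protein several times).

Query proteins resolved through several accession keys (their own plus
homologs') yield one vector per key; the per-key SVM scores are later
fused with convex weights, which for a linear kernel is equivalent to
scoring the single weighted-average vector computed by :func:`fuse`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VECTOR_MODES = ("tf", "binary")


class EmptySubspaceError(ValueError):
    """Raised when no GO term at all is available to span the subspace."""


class GOSubspace:
    """The ordered set of T distinct GO terms spanning the feature space.

    Terms are kept strictly sorted (lexicographically) so that models are
    reproducible regardless of input ordering.
    """

    __slots__ = ("terms", "_index")

    def __init__(self, terms: Iterable[str]):
        ordered = tuple(sorted(set(terms)))
        if not ordered:
            raise EmptySubspaceError("empty subspace: no GO terms supplied")
        self.terms = ordered
        self._index = {t: i for i, t in enumerate(ordered)}

    @property
    def T(self) -> int:
        return len(self.terms)

    def index(self, term: str) -> int:
        return self._index[term]

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GOSubspace):
            return NotImplemented
        return self.terms == other.terms

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GOSubspace(T={self.T})"

    def save(self, path) -> None:
        """Write the subspace as text: a ``T=<int>`` header then one id/line."""
        with open(path, "w") as fh:
            fh.write(f"T={self.T}\n")
            for term in self.terms:
                fh.write(term + "\n")

    @classmethod
    def load(cls, path) -> "GOSubspace":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("T="):
                raise ValueError("subspace file must start with a 'T=' header")
            declared = int(header[2:])
            terms = [ln.strip() for ln in fh if ln.strip()]
        if len(terms) != declared:
            raise ValueError(
                f"subspace header declares T={declared} but file has "
                f"{len(terms)} terms")
        return cls(terms)


def build_subspace(multisets: Iterable[Mapping[str, int]]) -> GOSubspace:
    """Union of all GO terms appearing in any training multiset, sorted.

    Raises :class:`EmptySubspaceError` when every multiset is empty.
    """
    union: set[str] = set()
    for ms in multisets:
        union.update(ms.keys())
    return GOSubspace(union)


@dataclass(frozen=True)
class GOVector:
    """A protein's coordinates in the GO subspace.

    ``mode`` is ``"tf"`` (occurrence counts) or ``"binary"`` (0/1 GO
    hits).  Values are a read-only 1-D float array of length T.
    """

    values: np.ndarray
    mode: str

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        if self.mode not in VECTOR_MODES:
            raise ValueError(f"unknown vector mode {self.mode!r}")
        if arr.ndim != 1:
            raise ValueError("GO vector must be one-dimensional")
        if (arr < 0).any():
            raise ValueError("GO vector coordinates must be non-negative")
        if self.mode == "binary" and not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("binary GO vector must contain only 0/1")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def is_zero(self) -> bool:
        return not self.values.any()

    def binarize(self) -> "GOVector":
        """Quantize term frequencies to 0/1 GO hits."""
        return GOVector((self.values > 0).astype(float), "binary")


def vectorize(multiset: Mapping[str, int], subspace: GOSubspace,
              mode: str = "tf", l2_normalize: bool = False) -> GOVector:
    """Project a GO-term multiset onto the subspace.

    TF mode stores the occurrence count of each subspace term; binary
    mode stores 1 iff the count is positive.  Terms outside the subspace
    are silently dropped (subspace selection); an empty multiset yields
    the zero vector.  ``l2_normalize`` rescales to unit Euclidean norm
    (off by default — raw counts are the canonical representation).
    """
    if mode not in VECTOR_MODES:
        raise ValueError(f"unknown vector mode {mode!r}")
    values = np.zeros(subspace.T)
    dropped = 0
    for term, count in multiset.items():
        if term in subspace:
            values[subspace.index(term)] = count
        else:
            dropped += count
    if dropped:
        logger.debug("vectorize: dropped %d out-of-subspace occurrence(s)",
                     dropped)
    if mode == "binary":
        values = (values > 0).astype(float)
    if l2_normalize:
        norm = np.linalg.norm(values)
        if norm > 0:
            values = values / norm
    return GOVector(values, mode)


def dropped_occurrences(multiset: Mapping[str, int],
                        subspace: GOSubspace) -> int:
    """Occurrences in ``multiset`` that fall outside the subspace."""
    return sum(c for t, c in multiset.items() if t not in subspace)


@dataclass(frozen=True)
class QueryVectorSet:
    """The GO vectors of one query's accession keys, with fusion weights.

    Vector 0 is the true-accession vector when present; the rest come
    from homologs.  Weights are non-negative and sum to one (within
    1e-12), so the fused score of a linear model is a convex combination
    of the per-key scores.
    """

    vectors: tuple
    weights: np.ndarray

    def __post_init__(self):
        vectors = tuple(self.vectors)
        weights = np.asarray(self.weights, dtype=float)
        weights.setflags(write=False)
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "weights", weights)
        if not vectors:
            raise ValueError("query set needs at least one vector")
        if len(vectors) != weights.shape[0]:
            raise ValueError("one weight per vector required")
        if (weights < 0).any():
            raise ValueError("fusion weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("fusion weights must sum to 1")
        lengths = {len(v) for v in vectors}
        if len(lengths) != 1:
            raise ValueError("all query vectors must share the subspace length")

    @property
    def matrix(self) -> np.ndarray:
        """Stacked query vectors, shape ``(k, T)``."""
        return np.stack([v.values for v in self.vectors])

    @property
    def is_zero(self) -> bool:
        """True when every key produced an all-zero vector."""
        return all(v.is_zero for v in self.vectors)

    def __len__(self) -> int:
        return len(self.vectors)


def make_query_set(keys: Sequence[str], table, subspace: GOSubspace,
                   mode: str = "tf", case: int | None = None,
                   l2_normalize: bool = False) -> QueryVectorSet:
    """Build the query's per-key GO vectors and their fusion weights.

    ``case`` mirrors the three input situations: 1 = accession only
    (single key, weight 1), 2 = sequence only (homolog keys, equal
    weights 1/n), 3 = accession plus homologs (true accession first,
    equal weights 1/(n+1)).  Weights are uniform over the keys actually
    present, so they always sum to one even when fewer homologs exist.
    An empty key list degenerates to a single zero vector with weight 1.
    """
    if case is not None:
        if case not in (1, 2, 3):
            raise ValueError("case must be 1, 2 or 3")
        if case == 1 and len(keys) != 1:
            raise ValueError("case 1 uses exactly one key (the true accession)")
        if case == 3 and len(keys) < 1:
            raise ValueError("case 3 needs the true accession key")
    if not keys:
        zero = GOVector(np.zeros(subspace.T), mode)
        return QueryVectorSet((zero,), np.array([1.0]))
    vectors = tuple(
        vectorize(table.terms(k), subspace, mode, l2_normalize) for k in keys)
    weights = np.full(len(keys), 1.0 / len(keys))
    return QueryVectorSet(vectors, weights)


def fuse(qs: QueryVectorSet) -> np.ndarray:
    """Coordinate-wise weighted sum of the query vectors.

    For a linear kernel, scoring this single fused vector equals the
    weighted sum of per-key scores (bilinearity), which is how the fused
    decision value can be computed in one kernel evaluation.
    """
    return qs.weights @ qs.matrix


def multiset_total(multiset: Mapping[str, int]) -> int:
    """Total occurrence count of a multiset (convenience for conservation)."""
    return sum(multiset.values())


def write_sparse_vectors(vectors: Mapping[str, GOVector],
                         subspace: GOSubspace, path) -> None:
    """Export GO vectors as sparse TSV rows: protein-id, term, count."""
    with open(path, "w") as fh:
        fh.write("#protein_id\tterm\tcount\n")
        for protein_id, vector in vectors.items():
            for i in np.flatnonzero(vector.values):
                count = vector.values[i]
                rendered = int(count) if count == int(count) else count
                fh.write(f"{protein_id}\t{subspace.terms[i]}\t{rendered}\n")
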