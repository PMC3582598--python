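"""Reading GO annotations, BLAST homology evidence and protein label files.

A protein's GO terms are looked up in a GAF-format annotation table keyed
by UniProtKB accession.  For proteins known only by sequence, the
accessions of BLAST homologs serve as surrogate search keys, and the GO
terms of the top-*n* homologs stand in for the protein's own annotation.

Term multiplicity is preserved throughout: the same GO term annotated to
one accession under several GAF entries counts several times.  These raw
occurrence counts are what the term-frequency feature vectors are built
from, so the table is a multiset store, not a set store.
"""

from __future__ import annotations

import csv
import gzip
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: Valid GO identifier: "GO:" followed by exactly seven digits.
GO_ID_PATTERN = re.compile(r"GO:\d{7}")

MODE_AC = "ac"
MODE_SEQ = "seq"
MODE_AC_SEQ = "ac+seq"
MODES = (MODE_AC, MODE_SEQ, MODE_AC_SEQ)


def _open_text(source) -> tuple[IO[str], bool]:
    """Open ``source`` as text, transparently handling gzip files.

    Returns the handle and whether the caller owns (must close) it.
    File-like objects are passed through untouched.
    """
    if hasattr(source, "read"):
        return source, False
    path = str(source)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt"), True
    return open(path, "rt"), True


class AnnotationTable:
    """Accession -> multiset of GO terms (the GO-annotation hash table).

    Looking up an accession that is absent returns an empty multiset
    rather than raising: an unannotated protein simply ends up with a
    zero GO vector downstream.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, int]] | None = None):
        self._entries: dict[str, Counter] = {}
        self.skipped_rows: int = 0
        if entries:
            for accession, terms in entries.items():
                for term, count in dict(terms).items():
                    self.add(accession, term, count)

    def add(self, accession: str, term: str, count: int = 1) -> None:
        if not GO_ID_PATTERN.fullmatch(term):
            raise ValueError(f"malformed GO id: {term!r}")
        if count < 1:
            raise ValueError(f"occurrence count must be >= 1, got {count}")
        self._entries.setdefault(accession, Counter())[term] += count

    def terms(self, accession: str) -> Counter:
        """Multiset of GO terms for ``accession`` (empty if unknown)."""
        return Counter(self._entries.get(accession, {}))

    def has_annotation(self, accession: str) -> bool:
        return bool(self._entries.get(accession))

    def accessions(self) -> Iterable[str]:
        return self._entries.keys()

    def total_occurrences(self) -> int:
        return sum(sum(c.values()) for c in self._entries.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"AnnotationTable({len(self)} accessions, "
            f"{self.total_occurrences()} occurrences)"
        )


def load_gaf(source, exclude_not: bool = False) -> AnnotationTable:
    """Parse a GAF 2.x stream into an :class:`AnnotationTable`.

    Only column 2 (accession) and column 5 (GO id) are consulted; one
    occurrence is counted per data row, and duplicate rows accumulate.
    Rows with fewer than 15 columns or a malformed GO id are skipped with
    a warning (the count of skipped rows is stored on the table).  An
    empty table is legal.

    Parameters
    ----------
    source:
        Path (plain or gzip) or text file-like object.
    exclude_not:
        When true, rows whose qualifier column contains ``NOT`` are
        ignored.  Off by default: no qualifier or evidence-code filtering
        is applied otherwise.
    """
    handle, owns = _open_text(source)
    table = AnnotationTable()
    skipped = 0
    try:
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                skipped += 1
                continue
            accession, qualifier, go_id = cols[1], cols[3], cols[4]
            if not accession or not GO_ID_PATTERN.fullmatch(go_id):
                skipped += 1
                continue
            if exclude_not and "NOT" in qualifier.split("|"):
                continue
            table.add(accession, go_id)
    finally:
        if owns:
            handle.close()
    if skipped:
        logger.warning("load_gaf: skipped %d malformed row(s)", skipped)
    table.skipped_rows = skipped
    return table


@dataclass(frozen=True)
class HomologHit:
    """One BLAST hit: subject accession, e-value and bit-score."""

    subject: str
    evalue: float
    bitscore: float


def _hit_key(hit: HomologHit):
    # Descending bit-score; ties by ascending e-value, then accession.
    return (-hit.bitscore, hit.evalue, hit.subject)


@dataclass
class HomologList:
    """BLAST hits for one query, best first.

    Hits are kept sorted by descending bit-score (ties broken by
    ascending e-value, then lexicographic subject accession); the query's
    own accession never appears.
    """

    query_id: str
    hits: list[HomologHit] = field(default_factory=list)

    def __post_init__(self):
        self.hits = sorted(self.hits, key=_hit_key)

    def top(self, n: int) -> list[str]:
        """Accessions of the best ``n`` homologs (fewer if fewer exist)."""
        return [h.subject for h in self.hits[:n]]

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[HomologHit]:
        return iter(self.hits)

    def __bool__(self) -> bool:
        return bool(self.hits)


def _iter_blast_rows(handle) -> Iterator[tuple[str, str, float, float]]:
    skipped = 0
    for line in handle:
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 12:
            skipped += 1
            continue
        try:
            evalue, bitscore = float(cols[10]), float(cols[11])
        except ValueError:
            skipped += 1
            continue
        yield cols[0], cols[1], evalue, bitscore
    if skipped:
        logger.warning("blast parser: skipped %d malformed row(s)", skipped)


def _dedupe(query_id: str, raw: Iterable[HomologHit],
            self_accession: str | None) -> HomologList:
    best: dict[str, HomologHit] = {}
    for hit in raw:
        if self_accession is not None and hit.subject == self_accession:
            continue
        incumbent = best.get(hit.subject)
        if incumbent is None or _hit_key(hit) < _hit_key(incumbent):
            best[hit.subject] = hit
    return HomologList(query_id, list(best.values()))


def parse_blast_tabular(source, query_id: str,
                        self_accession: str | None = None) -> HomologList:
    """Collect the homologs of one query from BLAST tabular (outfmt 6).

    The query's own accession is removed, duplicate subjects keep their
    best-bit-score row, and the result is sorted per the
    :class:`HomologList` invariant.
    """
    handle, owns = _open_text(source)
    try:
        raw = [HomologHit(s, e, b)
               for q, s, e, b in _iter_blast_rows(handle) if q == query_id]
    finally:
        if owns:
            handle.close()
    return _dedupe(query_id, raw, self_accession)


def load_blast_tabular(source,
                       self_accessions: Mapping[str, str] | None = None,
                       ) -> dict[str, HomologList]:
    """Parse a whole BLAST outfmt-6 file into per-query homolog lists.

    ``self_accessions`` maps query id -> that query's own accession so
    self-hits can be dropped.
    """
    handle, owns = _open_text(source)
    per_query: dict[str, list[HomologHit]] = {}
    try:
        for q, s, e, b in _iter_blast_rows(handle):
            per_query.setdefault(q, []).append(HomologHit(s, e, b))
    finally:
        if owns:
            handle.close()
    self_accessions = self_accessions or {}
    return {
        q: _dedupe(q, hits, self_accessions.get(q))
        for q, hits in per_query.items()
    }


def load_homolog_map(source) -> dict[str, HomologList]:
    """Read a precomputed homolog map TSV.

    Columns: query-id, rank (informational), subject-accession, e-value,
    bit-score.  Ranks in the file are ignored; the canonical bit-score
    ordering is re-imposed.
    """
    handle, owns = _open_text(source)
    per_query: dict[str, list[HomologHit]] = {}
    try:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 5:
                logger.warning("homolog map: skipped short row %r", row)
                continue
            query, _rank, subject, evalue, bitscore = row[:5]
            per_query.setdefault(query, []).append(
                HomologHit(subject, float(evalue), float(bitscore)))
    finally:
        if owns:
            handle.close()
    return {q: HomologList(q, hits) for q, hits in per_query.items()}


def write_homolog_map(homologs: Mapping[str, HomologList], path) -> None:
    """Serialize homolog lists to the homolog-map TSV format."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["#query", "rank", "subject", "evalue", "bitscore"])
        for query in sorted(homologs):
            for rank, hit in enumerate(homologs[query], start=1):
                writer.writerow(
                    [query, rank, hit.subject,
                     repr(hit.evalue), repr(hit.bitscore)])


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with its identifier, optional accession/sequence and labels.

    ``labels`` is the set of true subcellular-location indices (1-based);
    it is non-empty for training proteins and may be empty for queries.
    """

    protein_id: str
    accession: str | None = None
    sequence: str | None = None
    labels: frozenset = frozenset()

    def __post_init__(self):
        if self.accession is None and self.sequence is None:
            raise ValueError(
                f"{self.protein_id}: need at least one of accession/sequence")
        object.__setattr__(self, "labels", frozenset(self.labels))


def resolve_keys(protein: ProteinRecord, homologs: HomologList | None,
                 mode: str, n: int = 1) -> list[str]:
    """Ordered accession keys used to retrieve the protein's GO terms.

    Three input cases are supported: accession only (``"ac"``), sequence
    only (``"seq"``, top-``n`` homolog accessions), and both
    (``"ac+seq"``, the true accession followed by the top-``n`` homolog
    accessions).  When fewer than ``n`` homologs exist, a shorter list is
    returned; an empty list (sequence-only, no homologs) yields a zero
    GO vector downstream.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if n < 0:
        raise ValueError("n must be >= 0")
    if mode == MODE_AC:
        if protein.accession is None:
            raise ValueError(f"{protein.protein_id}: mode 'ac' needs an accession")
        return [protein.accession]
    hom_keys = homologs.top(n) if homologs else []
    if mode == MODE_SEQ:
        return hom_keys
    if protein.accession is None:
        raise ValueError(f"{protein.protein_id}: mode 'ac+seq' needs an accession")
    return [protein.accession] + hom_keys


def first_annotated_key(homologs: HomologList,
                        table: AnnotationTable) -> str | None:
    """Highest-ranked homolog with a non-empty GO multiset, else ``None``.

    Implements the homolog cascade used for novel proteins: when the top
    homolog carries no GO terms, fall through to the second-top, and so
    on.  ``None`` signals the caller to invoke its configured fallback.
    """
    for hit in homologs:
        if table.has_annotation(hit.subject):
            return hit.subject
    return None


def load_labels(source) -> tuple[list[tuple[str, frozenset]], list[str]]:
    """Read a label TSV: ``protein-id <TAB> label;label;...``.

    The first non-blank line must be a header naming the class catalog:
    ``#classes <TAB> name1;name2;...`` — its order defines the 1-based
    class indices (and hence M).  Labels in data rows may be class names
    or 1-based indices.  Rows with an empty label field yield an empty
    label set (queries).
    """
    handle, owns = _open_text(source)
    try:
        lines = [ln.rstrip("\n") for ln in handle]
    finally:
        if owns:
            handle.close()
    lines = [ln for ln in lines if ln.strip()]
    if not lines or not lines[0].startswith("#classes"):
        raise ValueError("label file must start with a '#classes' header")
    catalog = [c.strip() for c in lines[0].split("\t", 1)[1].split(";")]
    if len(set(catalog)) != len(catalog):
        raise ValueError("duplicate class names in catalog")
    index = {name: i + 1 for i, name in enumerate(catalog)}
    records: list[tuple[str, frozenset]] = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            continue
        parts = ln.split("\t")
        protein_id = parts[0]
        raw = parts[1] if len(parts) > 1 else ""
        labels = set()
        for token in filter(None, (t.strip() for t in raw.split(";"))):
            if token in index:
                labels.add(index[token])
            elif token.isdigit() and 1 <= int(token) <= len(catalog):
                labels.add(int(token))
            else:
                raise ValueError(f"unknown label {token!r} for {protein_id}")
        records.append((protein_id, frozenset(labels)))
    return records, catalog


def write_labels(records: Iterable[tuple[str, frozenset]],
                 class_names: list[str], path) -> None:
    """Write a label TSV (inverse of :func:`load_labels`), using names."""
    with open(path, "w") as fh:
        fh.write("#classes\t" + ";".join(class_names) + "\n")
        for protein_id, labels in records:
            names = ";".join(class_names[m - 1] for m in sorted(labels))
            fh.write(f"{protein_id}\t{names}\n")
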