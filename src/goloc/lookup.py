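"""Direct table-lookup localization baseline.

Some cellular-component GO terms denote a location class outright (the
*essential* terms), and their direct is_a/part_of descendants (*child*
terms) carry the same information one level down.  The baseline predicts
by matching the query's GO-term set against the essential terms of every
class first; only if no essential term matches does it fall back to the
child terms.  All classes matched within the winning tier are returned,
so a term set touching several classes produces a multi-label (often
over-predicted) answer; a set matching neither tier is "unpredictable"
(``None``), which the evaluator counts separately from an empty set.

A table for the six viral-protein locations ships with the package
(:func:`virus_lookup_table`); users may supply their own TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from .annotations import GO_ID_PATTERN, _open_text

logger = logging.getLogger(__name__)

ROLES = ("essential", "child")
RELATIONSHIPS = ("is_a", "part_of")


@dataclass
class LookupTable:
    """Essential and child GO terms per location class.

    ``essential`` maps class name -> set of essential GO ids;
    ``child`` maps class name -> {GO id: relationship}.  Within one
    class a GO id appears under a single role/relationship; across
    classes the same id may recur (which is precisely how the baseline
    over-predicts).
    """

    classes: list = field(default_factory=list)
    essential: dict = field(default_factory=dict)
    child: dict = field(default_factory=dict)

    def class_index(self, name: str) -> int:
        """1-based index of a class (catalog order of the table)."""
        return self.classes.index(name) + 1

    def n_terms(self, name: str) -> int:
        return len(self.essential.get(name, ())) + len(self.child.get(name, {}))


def load_lookup(source) -> LookupTable:
    """Parse a lookup-table TSV: class, go-id, role, relationship.

    ``role`` is ``essential`` or ``child``; ``relationship`` is ``is_a``
    or ``part_of`` for child rows and ``-`` for essential rows.  A
    duplicate (class, go-id) row keeps the first entry with a warning;
    an unknown role or relationship raises, naming the offending line.
    """
    handle, owns = _open_text(source)
    table = LookupTable()
    n_rows = 0
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise ValueError(f"line {lineno}: expected 4 columns")
            cls, go_id, role, relationship = (c.strip() for c in cols[:4])
            if not GO_ID_PATTERN.fullmatch(go_id):
                raise ValueError(f"line {lineno}: malformed GO id {go_id!r}")
            if role not in ROLES:
                raise ValueError(f"line {lineno}: unknown role {role!r}")
            if role == "child" and relationship not in RELATIONSHIPS:
                raise ValueError(
                    f"line {lineno}: unknown relationship {relationship!r}")
            if cls not in table.essential:
                table.classes.append(cls)
                table.essential[cls] = set()
                table.child[cls] = {}
            if go_id in table.essential[cls] or go_id in table.child[cls]:
                logger.warning(
                    "load_lookup: line %d duplicates (%s, %s); keeping the "
                    "first entry", lineno, cls, go_id)
                continue
            if role == "essential":
                table.essential[cls].add(go_id)
            else:
                table.child[cls][go_id] = relationship
            n_rows += 1
    finally:
        if owns:
            handle.close()
    if n_rows == 0:
        raise ValueError("empty lookup table")
    return table


def predict_lookup(go_terms: Iterable[str],
                   table: LookupTable) -> frozenset | None:
    """Predict location classes for a GO-term set by tiered matching.

    Essential-term matches across all classes are collected first; only
    when there is none are child-term matches consulted.  Returns the
    set of matched class names, or ``None`` when neither tier matches
    (the caller decides what "unpredictable" means).
    """
    terms = set(go_terms)
    essential_hits = frozenset(
        cls for cls in table.classes if terms & table.essential[cls])
    if essential_hits:
        return essential_hits
    child_hits = frozenset(
        cls for cls in table.classes if terms & table.child[cls].keys())
    if child_hits:
        return child_hits
    return None


def virus_lookup_table() -> LookupTable:
    """The packaged lookup table for the six viral-protein locations."""
    ref = resources.files("goloc.data").joinpath("virus_lookup_table.tsv")
    with ref.open() as fh:
        return load_lookup(fh)
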