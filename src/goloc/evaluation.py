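"""Multi-label evaluation: locative vs actual accuracy and friends.

A protein residing in k locations counts as k *locative* proteins but a
single *actual* protein.  With N_act actual proteins, of which n_act(m)
reside in exactly m locations,

    N_act = sum_m n_act(m)          N_loc = sum_m m * n_act(m).

The overall locative accuracy credits every correctly recovered
(protein, location) pair,

    Lambda_loc = (1 / N_loc) * sum_i |M(p_i) ∩ L(p_i)|,

while the overall actual accuracy is the stricter subset accuracy: a
protein counts only if its predicted set equals its true set exactly,

    Lambda_act = (1 / N_act) * sum_i [M(p_i) == L(p_i)].

A predictor that over-predicts can reach 100% locative accuracy while
its actual accuracy collapses (assigning every class to every protein
scores Lambda_loc = 1 and Lambda_act = 0 whenever no true set is the
full catalog), so the two are reported together, along with the
over-/equal-/under-prediction distribution of |M| - |L|.

Exact rationals (``fractions.Fraction``) are kept alongside floats so
that reports can render "hits/total = percent" cells losslessly.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

LabelSet = frozenset


def _normalize(pred) -> frozenset:
    """``None`` (unpredictable) is scored as the empty set."""
    return frozenset() if pred is None else frozenset(pred)


def _check_pair(true_sets, predicted_sets):
    if len(true_sets) != len(predicted_sets):
        raise ValueError("true and predicted lists must have equal length")
    for ls in true_sets:
        if not ls:
            raise ValueError("true label sets must be non-empty")


def count_proteins(label_sets: Sequence) -> tuple[int, int, dict]:
    """(N_act, N_loc, n_act) bookkeeping of a multi-label dataset.

    ``n_act`` maps multiplicity m -> number of actual proteins residing
    in exactly m locations.
    """
    for ls in label_sets:
        if not ls:
            raise ValueError("label sets must be non-empty")
    n_act = Counter(len(ls) for ls in label_sets)
    N_act = sum(n_act.values())
    N_loc = sum(m * c for m, c in n_act.items())
    return N_act, N_loc, dict(sorted(n_act.items()))


def locative_accuracy(true_sets: Sequence, predicted_sets: Sequence) -> Fraction:
    """Summed |predicted ∩ true| over the total number of locative proteins."""
    _check_pair(true_sets, predicted_sets)
    _, N_loc, _ = count_proteins(true_sets)
    hits = sum(len(_normalize(p) & frozenset(t))
               for t, p in zip(true_sets, predicted_sets))
    return Fraction(hits, N_loc)


def actual_accuracy(true_sets: Sequence, predicted_sets: Sequence) -> Fraction:
    """Fraction of proteins whose predicted set equals the true set exactly."""
    _check_pair(true_sets, predicted_sets)
    hits = sum(_normalize(p) == frozenset(t)
               for t, p in zip(true_sets, predicted_sets))
    return Fraction(hits, len(true_sets))


@dataclass
class PredictionDistribution:
    """Counts of proteins over-/equal-/under-predicted by k labels."""

    over: dict = field(default_factory=dict)    # k >= 1 -> count
    equal: dict = field(default_factory=dict)   # {0: count}
    under: dict = field(default_factory=dict)   # k >= 1 -> count

    @property
    def N_over(self) -> int:
        return sum(self.over.values())

    @property
    def N_equal(self) -> int:
        return sum(self.equal.values())

    @property
    def N_under(self) -> int:
        return sum(self.under.values())


def prediction_distribution(true_sets: Sequence,
                            predicted_sets: Sequence) -> PredictionDistribution:
    """Bucket every protein by k = | |predicted| - |true| | and its sign."""
    _check_pair(true_sets, predicted_sets)
    dist = PredictionDistribution()
    for t, p in zip(true_sets, predicted_sets):
        diff = len(_normalize(p)) - len(frozenset(t))
        if diff > 0:
            bucket, k = dist.over, diff
        elif diff < 0:
            bucket, k = dist.under, -diff
        else:
            bucket, k = dist.equal, 0
        bucket[k] = bucket.get(k, 0) + 1
    dist.over = dict(sorted(dist.over.items()))
    dist.under = dict(sorted(dist.under.items()))
    return dist


def per_class_locative(true_sets: Sequence, predicted_sets: Sequence,
                       M: int) -> dict:
    """Per-location locative accuracy: hits/total among proteins truly there."""
    _check_pair(true_sets, predicted_sets)
    result = {}
    for m in range(1, M + 1):
        total = sum(m in t for t in true_sets)
        hits = sum(m in t and m in _normalize(p)
                   for t, p in zip(true_sets, predicted_sets))
        result[m] = (hits, total)
    return result


def per_multiplicity_accuracy(true_sets: Sequence,
                              predicted_sets: Sequence) -> dict:
    """Exact-match fraction stratified by true multiplicity l = |L|.

    Strata with no proteins are absent from the result (never 0/0).
    """
    _check_pair(true_sets, predicted_sets)
    hits: Counter = Counter()
    totals: Counter = Counter()
    for t, p in zip(true_sets, predicted_sets):
        l = len(frozenset(t))
        totals[l] += 1
        hits[l] += _normalize(p) == frozenset(t)
    return {l: Fraction(hits[l], totals[l]) for l in sorted(totals)}


def _cell(hits: int, total: int) -> str:
    pct = 100.0 * hits / total if total else float("nan")
    return f"{hits}/{total} = {pct:.1f}%"


@dataclass
class EvalReport:
    """Full multi-label evaluation of one prediction run."""

    M: int
    N_act: int
    N_loc: int
    n_act: dict                       # multiplicity -> count of actual proteins
    locative: Fraction
    actual: Fraction
    per_class: dict                   # class index -> (hits, total)
    distribution: PredictionDistribution
    per_multiplicity: dict            # l -> Fraction
    n_unpredictable: int = 0
    class_names: list | None = None

    @property
    def locative_accuracy(self) -> float:
        return float(self.locative)

    @property
    def actual_accuracy(self) -> float:
        return float(self.actual)

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "N_act": self.N_act,
            "N_loc": self.N_loc,
            "n_act": {str(k): v for k, v in self.n_act.items()},
            "locative_accuracy": float(self.locative),
            "locative_accuracy_exact": f"{self.locative.numerator}/{self.locative.denominator}",
            "actual_accuracy": float(self.actual),
            "actual_accuracy_exact": f"{self.actual.numerator}/{self.actual.denominator}",
            "per_class": {
                str(m): {"hits": h, "total": t}
                for m, (h, t) in self.per_class.items()},
            "distribution": {
                "over": {str(k): v for k, v in self.distribution.over.items()},
                "equal": {str(k): v for k, v in self.distribution.equal.items()},
                "under": {str(k): v for k, v in self.distribution.under.items()},
                "N_over": self.distribution.N_over,
                "N_equal": self.distribution.N_equal,
                "N_under": self.distribution.N_under,
            },
            "per_multiplicity": {
                str(l): float(f) for l, f in self.per_multiplicity.items()},
            "n_unpredictable": self.n_unpredictable,
            "class_names": self.class_names,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        """Flat TSV rendering: metric, qualifier, hits, total, value."""
        rows = [
            ("N_act", "", "", "", self.N_act),
            ("N_loc", "", "", "", self.N_loc),
            ("locative_accuracy", "", self.locative.numerator,
             self.locative.denominator, float(self.locative)),
            ("actual_accuracy", "", self.actual.numerator,
             self.actual.denominator, float(self.actual)),
        ]
        for m, (h, t) in self.per_class.items():
            rows.append(("class_locative", m, h, t, h / t if t else ""))
        for l, f in self.per_multiplicity.items():
            rows.append(("actual_at_multiplicity", l, f.numerator,
                         f.denominator, float(f)))
        d = self.distribution
        for name, value in (("N_over", d.N_over), ("N_equal", d.N_equal),
                            ("N_under", d.N_under)):
            rows.append((name, "", "", "", value))
        with open(path, "w") as fh:
            fh.write("#metric\tqualifier\thits\ttotal\tvalue\n")
            for row in rows:
                fh.write("\t".join(str(c) for c in row) + "\n")

    def render(self) -> str:
        """Human-readable report with hits/total = percent cells."""
        names = self.class_names or [f"class {m}" for m in range(1, self.M + 1)]
        lines = [
            f"Actual proteins (N_act): {self.N_act}",
            f"Locative proteins (N_loc): {self.N_loc}",
            "Per-class locative accuracy:",
        ]
        for m in range(1, self.M + 1):
            h, t = self.per_class[m]
            lines.append(f"  {m}  {names[m - 1]}: {_cell(h, t)}")
        loc_hits = int(self.locative * self.N_loc)
        lines.append("Overall locative accuracy: " + _cell(loc_hits, self.N_loc))
        act_hits = int(self.actual * self.N_act)
        lines.append("Overall actual accuracy: " + _cell(act_hits, self.N_act))
        d = self.distribution
        lines.append(
            f"Over/equal/under-predicted: {d.N_over}/{d.N_equal}/{d.N_under} "
            f"of {self.N_act}")
        for l, f in self.per_multiplicity.items():
            total = self.n_act.get(l, 0)
            lines.append(f"Actual accuracy at l={l}: "
                         + _cell(int(f * total), total))
        if self.n_unpredictable:
            lines.append(f"Unpredictable proteins: {self.n_unpredictable}")
        return "\n".join(lines)


def evaluate(true_sets: Sequence, predicted_sets: Sequence, M: int,
             class_names: list | None = None) -> EvalReport:
    """Compute the full :class:`EvalReport` for one prediction run.

    ``predicted_sets`` entries may be ``None`` (a lookup-style
    "unpredictable" outcome); these are scored as empty sets — an
    under-prediction with no exact match — and counted separately.
    """
    _check_pair(true_sets, predicted_sets)
    true_sets = [frozenset(t) for t in true_sets]
    N_act, N_loc, n_act = count_proteins(true_sets)
    return EvalReport(
        M=M,
        N_act=N_act,
        N_loc=N_loc,
        n_act=n_act,
        locative=locative_accuracy(true_sets, predicted_sets),
        actual=actual_accuracy(true_sets, predicted_sets),
        per_class=per_class_locative(true_sets, predicted_sets, M),
        distribution=prediction_distribution(true_sets, predicted_sets),
        per_multiplicity=per_multiplicity_accuracy(true_sets, predicted_sets),
        n_unpredictable=sum(p is None for p in predicted_sets),
        class_names=class_names,
    )
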