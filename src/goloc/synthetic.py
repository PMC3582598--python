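"""Synthetic multi-label localization benchmarks.

Generates GAF annotation tables, BLAST-tabular homolog evidence and
multi-label protein sets in which each location class owns a block of
signature GO terms.  Proteins are annotated with the union of their
classes' signatures (with occurrence counts around a configurable
annotation depth), degraded by a noise dial, and every protein gets
synthetic homolog accessions carrying fidelity-degraded copies of its
annotation — so the whole pipeline, including the real GAF and BLAST
parsers, can be exercised without any database download.

The generator emulates the statistical structure the classifier relies
on — proteins sharing a location tend to share GO terms, with term
multiplicities carrying additional signal — not real GO-DAG topology or
amino-acid composition (sequences are random placeholders).

Everything is deterministic given the seed: each protein and homolog
draws from its own substream keyed by a stable hash of its accession,
so generation order is irrelevant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotations import AnnotationTable, HomologHit, HomologList, ProteinRecord
from .pipeline import Dataset

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Class names used by the virus-shaped packaged fixture.
VIRUS_CLASS_NAMES = (
    "Viral capsid", "Host cell membrane", "Host ER",
    "Host cytoplasm", "Host nucleus", "Secreted",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of one synthetic dataset.

    ``multiplicity`` gives the probabilities of a protein residing in
    l = 1, 2, ... locations; ``multiplicity_counts`` instead fixes the
    exact per-l counts (summing to N), as used by the packaged fixture.
    ``annotation_depth`` is the mean occurrence count per signature term
    (scalar, or one value per class so that depth itself carries class
    signal); ``signature_overlap`` makes consecutive classes share that
    many signature terms.  ``noise_rate`` both drops each signature-term
    annotation and adds each term of a disjoint noise pool with that
    probability.  ``homolog_fidelity`` is the probability that a homolog
    accession retains each of the protein's signature terms.
    """

    M: int = 6
    N: int = 207
    multiplicity: Sequence[float] = (0.80, 0.15, 0.05)
    multiplicity_counts: Sequence[int] | None = None
    signature_terms_per_class: int = 8
    signature_overlap: int = 0
    annotation_depth: float | Sequence[float] = 3.0
    noise_terms: int = 40
    noise_rate: float = 0.0
    homologs_per_protein: int = 1
    homolog_fidelity: float = 1.0
    seed: int = 0
    class_names: Sequence[str] | None = None

    def __post_init__(self):
        if self.M < 2:
            raise ValueError("need at least 2 classes")
        if self.N < 1:
            raise ValueError("need at least 1 protein")
        if self.multiplicity_counts is not None:
            counts = tuple(self.multiplicity_counts)
            if any(c < 0 for c in counts) or sum(counts) != self.N:
                raise ValueError("multiplicity_counts must be >= 0 and sum to N")
            if len(counts) > self.M:
                raise ValueError(
                    "multiplicity distribution allows more labels than classes")
        else:
            probs = tuple(self.multiplicity)
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("multiplicity probabilities must sum to 1")
            if len(probs) > self.M:
                raise ValueError(
                    "multiplicity distribution allows more labels than classes")
        if self.signature_terms_per_class < 1:
            raise ValueError("signature_terms_per_class must be >= 1")
        if not 0 <= self.signature_overlap < self.signature_terms_per_class:
            raise ValueError("signature_overlap must be in [0, terms-per-class)")
        for d in self.depths():
            if d < 1:
                raise ValueError("annotation_depth must be >= 1")
        if not 0 <= self.noise_rate <= 1:
            raise ValueError("noise_rate must be in [0, 1]")
        if not 0 <= self.homolog_fidelity <= 1:
            raise ValueError("homolog_fidelity must be in [0, 1]")
        if self.homologs_per_protein < 0:
            raise ValueError("homologs_per_protein must be >= 0")
        if self.class_names is not None and len(self.class_names) != self.M:
            raise ValueError("class_names must have one entry per class")

    def depths(self) -> tuple:
        """Per-class mean annotation depth."""
        if isinstance(self.annotation_depth, (int, float)):
            return (float(self.annotation_depth),) * self.M
        depths = tuple(float(d) for d in self.annotation_depth)
        if len(depths) != self.M:
            raise ValueError("annotation_depth must be scalar or length M")
        return depths

    def resolved_class_names(self) -> list:
        if self.class_names is not None:
            return list(self.class_names)
        return [f"loc{m}" for m in range(1, self.M + 1)]


def signature_terms(config: SyntheticConfig, class_index: int) -> list:
    """Signature GO terms of class ``class_index`` (1-based).

    Classes occupy consecutive index blocks; with a positive overlap,
    class m shares its trailing terms with class m + 1.
    """
    if not 1 <= class_index <= config.M:
        raise ValueError("class index out of range")
    k = config.signature_terms_per_class
    start = (class_index - 1) * (k - config.signature_overlap)
    return [f"GO:{1000000 + start + t:07d}" for t in range(k)]


def noise_pool(config: SyntheticConfig) -> list:
    """Noise GO terms, disjoint from every signature."""
    return [f"GO:{2000000 + i:07d}" for i in range(config.noise_terms)]


def _substream(seed: int, *parts) -> np.random.Generator:
    """Deterministic per-entity RNG keyed by a stable hash of ``parts``."""
    digest = hashlib.sha256("\x1f".join(str(p) for p in parts).encode()).digest()
    words = [int.from_bytes(digest[i:i + 4], "big") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([seed, *words]))


def _draw_label_sets(config: SyntheticConfig) -> list:
    rng = _substream(config.seed, "labels")
    if config.multiplicity_counts is not None:
        ls = [l + 1 for l, c in enumerate(config.multiplicity_counts)
              for _ in range(c)]
        rng.shuffle(ls)
    else:
        probs = np.asarray(config.multiplicity, dtype=float)
        probs = probs / probs.sum()
        ls = list(rng.choice(len(probs), size=config.N, p=probs) + 1)
    return [frozenset(int(m) for m in
                      rng.choice(config.M, size=int(l), replace=False) + 1)
            for l in ls]


def _annotate(counts: Counter, labels, config: SyntheticConfig,
              rng: np.random.Generator, keep_prob: float) -> None:
    """Add signature (kept with ``keep_prob``) and pool-noise terms."""
    depths = config.depths()
    for m in sorted(labels):
        for term in signature_terms(config, m):
            if rng.random() >= keep_prob:
                continue
            counts[term] += 1 + rng.poisson(depths[m - 1] - 1.0)
    for term in noise_pool(config):
        if rng.random() < config.noise_rate:
            counts[term] += 1


def _random_sequence(rng: np.random.Generator) -> str:
    length = 80 + int(rng.integers(0, 61))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def generate(config: SyntheticConfig) -> Dataset:
    """Generate a full synthetic dataset (proteins, GAF table, homologs)."""
    label_sets = _draw_label_sets(config)
    table = AnnotationTable()
    proteins, homologs = [], {}
    for i, labels in enumerate(label_sets):
        accession = f"SYNP{i:05d}"
        srng = _substream(config.seed, "sequence", accession)
        proteins.append(ProteinRecord(
            protein_id=accession, accession=accession,
            sequence=_random_sequence(srng), labels=labels))
        arng = _substream(config.seed, "annotation", accession)
        counts: Counter = Counter()
        _annotate(counts, labels, config, arng,
                  keep_prob=1.0 - config.noise_rate)
        for term, count in sorted(counts.items()):
            table.add(accession, term, count)
        hits = []
        for j in range(1, config.homologs_per_protein + 1):
            hom_accession = f"SYNH{i:05d}_{j}"
            hrng = _substream(config.seed, "homolog", hom_accession)
            hom_counts: Counter = Counter()
            _annotate(hom_counts, labels, config, hrng,
                      keep_prob=config.homolog_fidelity)
            for term, count in sorted(hom_counts.items()):
                table.add(hom_accession, term, count)
            hits.append(HomologHit(
                subject=hom_accession,
                evalue=10.0 ** -(90 - 10 * (j - 1)),
                bitscore=250.0 - 30.0 * (j - 1)))
        homologs[accession] = HomologList(accession, hits)
    return Dataset(proteins=proteins, annotations=table, homologs=homologs,
                   class_names=config.resolved_class_names())


def virus_like_fixture(seed: int = 7) -> Dataset:
    """Packaged deterministic dataset with the virus benchmark's shape.

    Six location classes, 207 proteins of which 165/39/3 reside in
    1/2/3 locations (so 252 locative proteins), disjoint class
    signatures, no noise, one perfectly faithful homolog per protein.
    Contents are synthetic; only the shape mirrors the benchmark.
    """
    return generate(virus_like_config(seed))


def virus_like_config(seed: int = 7) -> SyntheticConfig:
    return SyntheticConfig(
        M=6, N=207, multiplicity_counts=(165, 39, 3),
        signature_terms_per_class=8, signature_overlap=0,
        annotation_depth=3.0, noise_terms=40, noise_rate=0.0,
        homologs_per_protein=1, homolog_fidelity=1.0,
        seed=seed, class_names=VIRUS_CLASS_NAMES)


# -- file emission ---------------------------------------------------------

GAF_DATE = "20110308"


def write_gaf(table: AnnotationTable, path) -> None:
    """Write an annotation table as GAF 2.2 (one row per occurrence)."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for accession in sorted(table.accessions()):
            for term, count in sorted(table.terms(accession).items()):
                row = ["SYN", accession, accession, "located_in", term,
                       "SYN_REF:0000001", "IEA", "", "C", "", "", "protein",
                       "taxon:0", GAF_DATE, "SYN", "", ""]
                for _ in range(count):
                    fh.write("\t".join(row) + "\n")


def write_blast_tabular(dataset: Dataset, path) -> None:
    """Write homolog evidence as BLAST outfmt 6, self-hit included.

    The self-hit row exercises the parser's self-accession removal; hit
    rows carry fabricated alignment columns (only e-value and bit-score
    matter downstream).
    """
    with open(path, "w") as fh:
        for protein in dataset.proteins:
            length = len(protein.sequence or "") or 100
            fh.write("\t".join(map(str, [
                protein.protein_id, protein.accession, "100.000", length,
                0, 0, 1, length, 1, length, "0.0", "500"])) + "\n")
            for hit in dataset.get_homologs(protein.protein_id):
                fh.write("\t".join(map(str, [
                    protein.protein_id, hit.subject, "45.000", length,
                    length // 2, 3, 1, length, 1, length,
                    f"{hit.evalue:.3g}", f"{hit.bitscore:.1f}"])) + "\n")


def write_fasta(dataset: Dataset, path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="synthetic")
        for p in dataset.proteins if p.sequence]
    SeqIO.write(records, str(path), "fasta")


def write_manifest(config: SyntheticConfig, path, extra: dict | None = None) -> None:
    payload = dataclasses.asdict(config)
    for key, value in list(payload.items()):
        if isinstance(value, tuple):
            payload[key] = list(value)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
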