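import io
import textwrap

import pytest
from hypothesis import HealthCheck, settings

from goloc import load_gaf, virus_lookup_table
from goloc.synthetic import SyntheticConfig, generate, virus_like_fixture

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def gaf_stream(rows, header: bool = True) -> io.StringIO:
    """Build a GAF 2.2 text stream from (accession, go_id) pairs."""
    lines = ["!gaf-version: 2.2"] if header else []
    for accession, go_id in rows:
        cols = ["DB", accession, accession, "located_in", go_id,
                "REF:1", "IEA", "", "C", "", "", "protein",
                "taxon:1", "20110308", "DB", "", ""]
        lines.append("\t".join(cols))
    return io.StringIO("\n".join(lines) + "\n")


@pytest.fixture
def small_table():
    return load_gaf(gaf_stream([
        ("P1", "GO:0000001"),
        ("P1", "GO:0000001"),
        ("P1", "GO:0000002"),
        ("P2", "GO:0000002"),
        ("P2", "GO:0000003"),
        ("H1", "GO:0000001"),
    ]))


@pytest.fixture(scope="session")
def lookup_table():
    return virus_lookup_table()


@pytest.fixture(scope="session")
def virus_fixture():
    return virus_like_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """Separable synthetic set: 3 classes, 30 proteins, clean annotations."""
    return generate(SyntheticConfig(
        M=3, N=30, multiplicity=(0.7, 0.3), signature_terms_per_class=5,
        homologs_per_protein=2, seed=11))


BLAST_COLUMNS = ("qseqid sseqid pident length mismatch gapopen qstart qend "
                 "sstart send evalue bitscore").split()


def blast_row(qseqid, sseqid, evalue, bitscore) -> str:
    return "\t".join(map(str, [qseqid, sseqid, 50.0, 100, 40, 2, 1, 100,
                               1, 100, evalue, bitscore]))


def blast_stream(rows) -> io.StringIO:
    return io.StringIO("\n".join(blast_row(*r) for r in rows) + "\n")
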