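import pytest

from zeinpep.motif_db import build_fixture, fixture_path
from zeinpep.sequences import read_fasta


@pytest.fixture(scope="session")
def printed_records():
    """The six printed alpha-zein sequences, keyed by accession."""
    return {r.accession: r for r in read_fasta(fixture_path("alpha_zein_printed.fasta"))}


@pytest.fixture(scope="session")
def fixture_db():
    """The packaged motif database (union of the printed per-protein tables)."""
    return build_fixture()


def brute_force_occurrences(sequence: str, motif: str) -> list[int]:
    """Independent oracle: check every start position explicitly."""
    return [
        i for i in range(len(sequence) - len(motif) + 1)
        if sequence[i:i + len(motif)] == motif
    ]
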