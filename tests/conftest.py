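from pathlib import Path

import pytest

from stemscan import tgfb1
from stemscan.folding import FoldConfig

#: Directory where a user may drop downloaded accession FASTAs
#: (NM_000660.fasta etc.) to enable the full-UTR and cross-species checks.
ACCESSION_DIR = Path(__file__).parent / "data" / "accessions"


@pytest.fixture(scope="session")
def endo():
    return tgfb1.endogenous_insert()


@pytest.fixture(scope="session")
def mutant_records():
    return tgfb1.mutant_inserts()


@pytest.fixture(scope="session")
def thermo():
    return FoldConfig(backend="thermodynamic")


@pytest.fixture(scope="session")
def reference():
    return FoldConfig(backend="reference")


def accession_record(name: str):
    """Load a user-supplied accession FASTA, or skip the requesting test."""
    from stemscan.sequences import read_fasta

    path = ACCESSION_DIR / f"{name}.fasta"
    if not path.exists():
        pytest.skip(
            f"requires user-supplied {name} FASTA at {path} "
            "(accessions are never fetched automatically)"
        )
    return read_fasta(path)[0]
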