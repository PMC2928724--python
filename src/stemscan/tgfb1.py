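"""Reconstruction of the TGF-beta1 5'UTR +1..+167 inserts from printed oligos.

The proximal 167 nt of the human TGF-beta1 5'UTR (reference transcript
NM_000660) and five adenine-substitution mutants of its stem-loop /
protein-binding-site region were cloned from pairs of long overlapping
oligonucleotides whose sequences are printed in the original construct
table.  Those oligos are shipped here as a packaged FASTA fixture, which
makes the whole insert family reconstructible offline.

Coordinate landmarks (the +1 frame of NM_000660's 5'UTR):

* ``STEM_LOOP = (77, 106)`` - the G/C-rich hairpin element.
* ``COMPOSITION_WINDOW = (59, 138)`` - the 80-nt window whose composition is
  exactly 36 G, 36 C, 4 A, 4 U.
* ``MUTANT_REGIONS`` - the adenine-substituted interval of each construct.

The endogenous insert never appears verbatim in the table; it is spliced
together from two mutant sense oligos.  The pGL3-50/56A sense oligo is
endogenous everywhere except +50..+56, and the pGL3-92/105A sense oligo is
endogenous through +91, so restoring +50..+56 from the latter yields a fully
endogenous sense strand, which is then extended through the pGL3-50/56A
antisense oligo.

One printed-table nuance: the pGL3-92/98A sense oligo carries an eight-
adenine run spanning +92..+99 even though the construct name claims a
seven-position substitution.  Position +99 is endogenously adenine, so the
assembled insert is nevertheless exactly the 92..98 A-substitution of the
endogenous sequence; :func:`check_table_consistency` verifies this rather
than silently assuming it.
"""

from __future__ import annotations

from importlib import resources

from .errors import AssemblyError
from .sequences import (
    OligoPair,
    SequenceRecord,
    apply_substitution,
    assemble_insert,
)

STEM_LOOP = (77, 106)
COMPOSITION_WINDOW = (59, 138)
INSERT_LENGTH = 167

#: Adenine-substituted interval of each construct, in +1 coordinates.
MUTANT_REGIONS: dict[str, tuple[int, int]] = {
    "pGL3-77/105A": (77, 105),
    "pGL3-92/105A": (92, 105),
    "pGL3-92/98A": (92, 98),
    "pGL3-99/105A": (99, 105),
    "pGL3-50/56A": (50, 56),
}

_SPLICE_DONOR = "pGL3-92/105A"  # endogenous through +91
_SPLICE_ACCEPTOR = "pGL3-50/56A"  # endogenous except +50..+56
_ADAPTER_LEN = 8  # leading cc + HindIII clamp on every sense oligo


def _read_raw_fasta(text: str) -> dict[str, str]:
    """Parse FASTA preserving case (mutated residues are capitalised)."""
    entries: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:]
            entries[name] = ""
        else:
            entries[name] += line
    return entries


def table1_oligos() -> dict[str, OligoPair]:
    """The five mutant-construct oligo pairs from the packaged fixture."""
    text = resources.files("stemscan").joinpath("data/table1_oligos.fasta").read_text()
    raw = _read_raw_fasta(text)
    pairs: dict[str, OligoPair] = {}
    for name in MUTANT_REGIONS:
        pairs[name] = OligoPair(
            name=name, sense=raw[f"{name}|sense"], antisense=raw[f"{name}|antisense"]
        )
    return pairs


def pcr_primers() -> dict[str, tuple[str, str]]:
    """The +1..+167 and +1..+840 amplification primer pairs (sense, antisense)."""
    text = resources.files("stemscan").joinpath("data/table1_oligos.fasta").read_text()
    raw = _read_raw_fasta(text)
    return {
        name: (raw[f"{name}|sense"], raw[f"{name}|antisense"])
        for name in ("pGL3-167", "pGL3-840")
    }


def endogenous_insert() -> SequenceRecord:
    """The endogenous +1..+167 insert, spliced from two mutant sense oligos."""
    pairs = table1_oligos()
    acceptor = pairs[_SPLICE_ACCEPTOR]
    donor = pairs[_SPLICE_DONOR]
    a_start, a_end = MUTANT_REGIONS[_SPLICE_ACCEPTOR]
    lo = _ADAPTER_LEN + a_start - 1
    hi = _ADAPTER_LEN + a_end
    sense = acceptor.sense[:lo] + donor.sense[lo:hi] + acceptor.sense[hi:]
    record = assemble_insert(
        OligoPair(name="TGFB1-5UTR-167", sense=sense, antisense=acceptor.antisense)
    )
    if len(record) != INSERT_LENGTH:
        raise AssemblyError(
            f"endogenous insert assembled to {len(record)} nt, expected {INSERT_LENGTH}"
        )
    return SequenceRecord(
        id="TGFB1-5UTR-167",
        residues=record.residues,
        offset=1,
        source="assembled from construct-table oligos (NM_000660 +1..+167)",
    )


def mutant_inserts() -> dict[str, SequenceRecord]:
    """All five mutant +1..+167 inserts assembled from their oligo pairs."""
    return {name: assemble_insert(pair) for name, pair in table1_oligos().items()}


def check_table_consistency() -> dict[str, bool]:
    """Verify each assembled mutant equals the A-substitution of the endogenous insert.

    Returns a per-construct boolean map; any ``False`` marks a genuine
    discrepancy between the printed oligos and the construct's name.
    """
    endo = endogenous_insert()
    out: dict[str, bool] = {}
    for name, rec in mutant_inserts().items():
        start, end = MUTANT_REGIONS[name]
        expected = apply_substitution(endo, start, end, "A")
        out[name] = rec.residues == expected.residues
    return out
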