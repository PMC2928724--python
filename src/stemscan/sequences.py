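"""Sequence records, FASTA I/O, coordinates and oligonucleotide assembly.

All public coordinates are 1-based inclusive intervals in the "+1" frame of
the parent transcript: position ``offset`` is the first residue of a record,
so a record with ``offset=59`` holds positions +59 onward.  Sequences are held
as RNA (``A C G U``); DNA input is accepted everywhere and normalised by the
``T -> U`` substitution.

Besides generic plumbing (reading/writing FASTA, reverse complement, region
extraction, residue composition) this module implements the reconstruction of
cloned 5'UTR inserts from pairs of long overlapping oligonucleotides: the two
oligos anneal over a complementary 3' region and are extended to a full
duplex, after which the restriction-site adapters (a HindIII clamp on the
sense end, an NcoI site carrying the downstream initiator context on the
antisense end) are trimmed away so that the first retained residue is +1.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import AlphabetError, AssemblyError, BoundsError, FastaFormatError

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT_RNA = str.maketrans("ACGU", "UGCA")
_COMPLEMENT_DNA = str.maketrans("acgtACGT", "tgcaTGCA")

#: Leading adapter on sense oligos: a cc clamp followed by the HindIII site.
HINDIII_ADAPTER = "ccaagctt"

#: Trailing adapter left on the sense strand after extension through the
#: antisense oligo's NcoI end.  The NcoI site (ccatgg) supplies the initiator
#: AUG of the downstream reporter, so the whole c{2,}atg{2,} run is vector
#: context, not UTR.
_NCOI_TAIL = re.compile(r"c{2,}atg{2,}$")


def normalise_rna(residues: str) -> str:
    """Upper-case ``residues`` and convert DNA thymine to uracil."""
    return residues.upper().replace("T", "U")


@dataclass(frozen=True)
class SequenceRecord:
    """An identified RNA sequence anchored to transcript coordinates.

    ``offset`` is the 1-based position, in the parent transcript's +1
    numbering, of the first residue.
    """

    id: str
    residues: str
    offset: int = 1
    source: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"record {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: invalid residues {sorted(bad)} "
                "(IUPAC ambiguity codes are rejected; use A/C/G/U)"
            )
        if self.offset < 1:
            raise BoundsError(f"record {self.id!r}: offset must be >= 1, got {self.offset}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> int:
        return self.offset

    @property
    def end(self) -> int:
        """1-based inclusive coordinate of the last residue."""
        return self.offset + len(self.residues) - 1

    @classmethod
    def from_dna(cls, id: str, dna: str, offset: int = 1, source: str = "") -> "SequenceRecord":
        return cls(id=id, residues=normalise_rna(dna), offset=offset, source=source)


@dataclass(frozen=True)
class OligoPair:
    """Two overlapping DNA oligonucleotides, both written 5'->3'.

    The 3' end of the sense oligo is complementary to the 3' end of the
    antisense oligo over at least ``min_overlap`` residues, which is what
    lets a polymerase extend the annealed pair into a full duplex.
    Case is preserved as given (the printed construct tables capitalise
    substituted residues).
    """

    name: str
    sense: str
    antisense: str
    sense_adapter: str = HINDIII_ADAPTER
    antisense_adapter: str = "ccccatggg"
    min_overlap: int = 8

    def __post_init__(self) -> None:
        if self.overlap_length() < self.min_overlap:
            raise AssemblyError(
                f"{self.name}: sense/antisense 3' ends share no complementary "
                f"overlap of length >= {self.min_overlap}"
            )

    def overlap_length(self) -> int:
        ranti = reverse_complement_dna(self.antisense).lower()
        sense = self.sense.lower()
        for ov in range(min(len(sense), len(ranti)), 0, -1):
            if sense[-ov:] == ranti[:ov]:
                return ov
        return 0


@dataclass(frozen=True)
class CompositionTable:
    """Residue counts over a 1-based inclusive region of a record."""

    counts: Mapping[str, int]
    region: tuple[int, int]
    gc_fraction: float = field(default=0.0)

    def __post_init__(self) -> None:
        start, end = self.region
        length = end - start + 1
        total = sum(self.counts.values())
        if total != length:
            raise ValueError(f"counts sum to {total}, region length is {length}")

    @property
    def length(self) -> int:
        return self.region[1] - self.region[0] + 1


def reverse_complement(seq: SequenceRecord) -> SequenceRecord:
    """Watson-Crick complement (A<->U, G<->C) in reversed order."""
    return replace(seq, residues=seq.residues.translate(_COMPLEMENT_RNA)[::-1])


def reverse_complement_dna(dna: str) -> str:
    """Reverse complement of a DNA string, preserving case."""
    return dna.translate(_COMPLEMENT_DNA)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records; T/t normalised to U, case folded up.

    Raises :class:`FastaFormatError` naming the offending line for an empty
    file or sequence data appearing before the first header.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush(lineno: int) -> None:
        if header is None:
            return
        if not chunks:
            raise FastaFormatError(f"{path}: entry {header!r} before line {lineno} has no sequence")
        records.append(SequenceRecord.from_dna(header, "".join(chunks), source=str(path)))

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before any '>' header at line {lineno}"
                    )
                chunks.append(line)
        if header is None:
            raise FastaFormatError(f"{path}: no FASTA entries found (line {lineno})")
        flush(lineno + 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with ``width``-column wrapped sequence lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _dna_space(s: str) -> str:
    return s.lower().replace("u", "t")


def trim_adapters(
    seq: SequenceRecord,
    adapters: tuple[str, str] = (HINDIII_ADAPTER, "ccatgg"),
) -> tuple[SequenceRecord, tuple[int, int]]:
    """Strip restriction-site adapters from both ends of ``seq``.

    The leading adapter (clamp + HindIII, ``ccaagctt``) is removed when
    present at the 5' end.  At the 3' end the maximal suffix of the form
    ``c..catg..g`` containing the NcoI site given in ``adapters[1]`` is
    removed: the NcoI site carries the initiator AUG of the downstream
    reporter, so everything from its leading cytosines onward is vector
    context.  The offset is reset so the first remaining residue is +1.

    Returns the trimmed record plus the removed lengths ``(left, right)``.
    An expected-but-absent adapter triggers a warning, not an error.
    """
    lead, ncoi = adapters
    residues = seq.residues
    s = _dna_space(residues)

    left = 0
    if s.startswith(_dna_space(lead)):
        left = len(lead)
    else:
        warnings.warn(f"{seq.id}: leading adapter {lead!r} not found; left end unchanged")

    right = 0
    tail_limit = min(len(s) - left, 16)
    for k in range(tail_limit, len(ncoi) - 1, -1):
        suffix = s[len(s) - k :]
        if _NCOI_TAIL.fullmatch(suffix) and _dna_space(ncoi) in suffix:
            right = k
            break
    if right == 0:
        warnings.warn(f"{seq.id}: trailing NcoI adapter not found; right end unchanged")

    trimmed = residues[left : len(residues) - right]
    if not trimmed:
        raise AssemblyError(f"{seq.id}: adapters cover the entire sequence")
    return replace(seq, residues=trimmed, offset=1), (left, right)


def assemble_insert(pair: OligoPair, trim: bool = True) -> SequenceRecord:
    """Anneal/extend an oligo pair and return the sense strand of the product.

    The two oligos anneal over the longest exact complementary 3' overlap
    (minimum 8 nt, no mismatches tolerated); the sense strand of the
    extension product is the sense oligo extended 3' by the reverse
    complement of the antisense oligo's non-overlapping 5' portion.  With
    ``trim`` the restriction-site adapters are removed so the record spans
    +1 onward of the cloned insert.
    """
    ov = pair.overlap_length()
    if ov < pair.min_overlap:
        candidates = [
            k
            for k in range(1, pair.min_overlap)
            if pair.sense.lower()[-k:] == reverse_complement_dna(pair.antisense).lower()[:k]
        ]
        raise AssemblyError(
            f"{pair.name}: no complementary 3' overlap >= {pair.min_overlap} nt "
            f"(candidate overlaps: {candidates or 'none'})"
        )
    ranti = reverse_complement_dna(pair.antisense)
    product = pair.sense + ranti[ov:]
    record = SequenceRecord.from_dna(
        pair.name, product, source=f"anneal/extension of {pair.name} oligos (overlap {ov} nt)"
    )
    if trim:
        record, _removed = trim_adapters(record)
    return record


def _check_region(seq: SequenceRecord, start: int, end: int) -> None:
    if not (seq.start <= start <= end <= seq.end):
        raise BoundsError(
            f"{seq.id}: region {start}..{end} outside valid interval "
            f"{seq.start}..{seq.end}"
        )


def extract_region(seq: SequenceRecord, start: int, end: int) -> SequenceRecord:
    """Subsequence over the 1-based inclusive interval ``start..end``.

    Coordinates are interpreted in the record's own frame (its ``offset``);
    the returned record's offset is ``start``.
    """
    _check_region(seq, start, end)
    lo = start - seq.offset
    hi = end - seq.offset + 1
    return replace(
        seq,
        id=f"{seq.id}:{start}-{end}",
        residues=seq.residues[lo:hi],
        offset=start,
    )


def composition(seq: SequenceRecord, region: tuple[int, int] | None = None) -> CompositionTable:
    """Exact residue counts and G+C fraction over ``region`` (default: all)."""
    if region is None:
        region = (seq.start, seq.end)
    start, end = region
    _check_region(seq, start, end)
    sub = seq.residues[start - seq.offset : end - seq.offset + 1]
    counts = Counter(sub)
    for base in RNA_ALPHABET:
        counts.setdefault(base, 0)
    gc = (counts["G"] + counts["C"]) / len(sub)
    return CompositionTable(counts=dict(counts), region=(start, end), gc_fraction=gc)


def apply_substitution(
    seq: SequenceRecord, start: int, end: int, residue: str = "A"
) -> SequenceRecord:
    """Replace every position in ``start..end`` with ``residue``.

    The construct is named ``<id>-<start>/<end><residue>`` after the cloning
    convention for adenine-substitution mutants.
    """
    residue = normalise_rna(residue)
    if len(residue) != 1 or residue not in RNA_ALPHABET:
        raise AlphabetError(f"substitution residue must be one of A/C/G/U, got {residue!r}")
    _check_region(seq, start, end)
    lo = start - seq.offset
    hi = end - seq.offset + 1
    mutated = seq.residues[:lo] + residue * (hi - lo) + seq.residues[hi:]
    return replace(seq, id=f"{seq.id}-{start}/{end}{residue}", residues=mutated)


def composition_tsv(tables: Sequence[tuple[str, CompositionTable]]) -> str:
    """Render (id, CompositionTable) pairs as the documented TSV layout."""
    lines = ["id\tstart\tend\tA\tC\tG\tU\tgc_fraction"]
    for rec_id, tab in tables:
        start, end = tab.region
        lines.append(
            f"{rec_id}\t{start}\t{end}\t{tab.counts['A']}\t{tab.counts['C']}\t"
            f"{tab.counts['G']}\t{tab.counts['U']}\t{tab.gc_fraction:.6g}"
        )
    return "\n".join(lines) + "\n"
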