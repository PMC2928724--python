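"""Sequence I/O, coordinates, and reconstruction of the cloned inserts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from stemscan import tgfb1
from stemscan.errors import AssemblyError, BoundsError, FastaFormatError
from stemscan.sequences import (
    HINDIII_ADAPTER,
    OligoPair,
    SequenceRecord,
    apply_substitution,
    assemble_insert,
    composition,
    extract_region,
    read_fasta,
    reverse_complement,
    reverse_complement_dna,
    trim_adapters,
    write_fasta,
)

rna_text = st.text(alphabet="ACGU", min_size=1, max_size=60)


class TestFastaIO:
    def test_t_normalised_to_u(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACGT\n")
        (rec,) = read_fasta(p)
        assert rec.residues == "ACGU"

    def test_round_trip_identity(self, tmp_path):
        records = [
            SequenceRecord("a", "ACGUACGUACGU" * 12),
            SequenceRecord("b", "GGGCCC"),
        ]
        p = tmp_path / "rt.fasta"
        write_fasta(records, p)
        back = read_fasta(p)
        assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in records]

    def test_mixed_case_multi_entry_matches_naive_scan(self, tmp_path):
        text = ">one\nacgTAcg\nGGcc\n>two desc ignored\nuuuAAA\n>three\ngattaca\n"
        p = tmp_path / "m.fasta"
        p.write_text(text)
        expected = _oracles.naive_fasta_scan(text)
        got = [(r.id, r.residues) for r in read_fasta(p)]
        assert got == expected

    @pytest.mark.parametrize(
        "content", ["", "ACGT\n>late header\nACGT\n", ">\nACGU\n"],
        ids=["empty", "sequence-before-header", "blank-header"],
    )
    def test_malformed_files_raise_naming_the_line(self, tmp_path, content):
        p = tmp_path / "bad.fasta"
        p.write_text(content)
        with pytest.raises(FastaFormatError, match=str(p)):
            read_fasta(p)


class TestReverseComplement:
    def test_acgu_is_its_own_reverse_complement(self):
        assert reverse_complement(SequenceRecord("x", "ACGU")).residues == "ACGU"

    @settings(max_examples=50, derandomize=True)
    @given(rna_text)
    def test_involution(self, residues):
        rec = SequenceRecord("x", residues)
        assert reverse_complement(reverse_complement(rec)).residues == residues

    def test_antisense_tail_occurs_in_endogenous_sense_prefix(self):
        # The 3' tail of the pGL3-92/105A antisense oligo reads back into
        # the endogenous sequence; its reverse complement must therefore
        # occur verbatim in the endogenous region of the sense oligos.
        pairs = tgfb1.table1_oligos()
        tail = pairs["pGL3-92/105A"].antisense[-23:]
        assert tail.lower() == "acggggcgtcccccctgcccccg"
        rc_tail = reverse_complement_dna(tail).lower()
        assert rc_tail in pairs["pGL3-50/56A"].sense.lower()


class TestAdapters:
    def test_leading_hindiii_clamp_removed(self):
        rec = SequenceRecord.from_dna("x", "ccaagctt" + "CCTTCGCGCCCTGGGCCATCT")
        trimmed, removed = trim_adapters(rec)
        assert trimmed.residues.startswith("CCUUCG")
        assert removed[0] == 8

    def test_sequence_without_adapters_unchanged(self):
        rec = SequenceRecord("x", "CCUUCGCGCCCUGGGCCAUCU")
        with pytest.warns(UserWarning):
            trimmed, removed = trim_adapters(rec)
        assert trimmed.residues == rec.residues
        assert removed == (0, 0)

    def test_both_end_adapters_on_toy_40mer(self):
        interior = "GAUUACAGAUUACAGAUUACAGAU"  # 24-mer
        rec = SequenceRecord.from_dna("toy", "ccaagctt" + interior + "ccatgggg")
        trimmed, removed = trim_adapters(rec)
        assert trimmed.residues == interior
        assert removed == (8, 8)
        assert trimmed.offset == 1


class TestAssembly:
    def test_endogenous_assembly_is_167nt_with_printed_prefix(self, endo):
        assert len(endo) == 167
        assert endo.residues[:21] == "CCUUCGCGCCCUGGGCCAUCU"

    def test_fully_complementary_pair_gives_zero_extension(self):
        sense = "GATTACAGATTACAGATTACAG"
        pair = OligoPair("toy", sense, reverse_complement_dna(sense))
        product = assemble_insert(pair, trim=False)
        assert product.residues == sense.upper().replace("T", "U")

    def test_toy_pair_with_10nt_overlap_matches_hand_extension(self):
        # sense 18-mer and antisense 18-mer overlapping over 10 nt -> 26-mer
        full = "GATTACAGGCCTTGGAACCTTGGCAT"  # hand-written target duplex
        sense, antisense = full[:18], reverse_complement_dna(full[-18:])
        product = assemble_insert(OligoPair("toy", sense, antisense), trim=False)
        assert product.residues == full.replace("T", "U")

    def test_no_overlap_is_an_assembly_error(self):
        with pytest.raises(AssemblyError):
            OligoPair("bad", "GGGGGGGGGGGG", "GGGGGGGGGGGG")

    def test_every_mutant_insert_is_167nt(self, mutant_records):
        assert {len(r) for r in mutant_records.values()} == {167}

    def test_sense_oligos_agree_with_endogenous_outside_mutated_regions(self, endo):
        # Wherever a sense oligo covers endogenous positions, it must agree
        # residue-for-residue with the assembled insert.
        for name, pair in tgfb1.table1_oligos().items():
            start, end = tgfb1.MUTANT_REGIONS[name]
            insert_part = pair.sense[8:]  # drop HindIII clamp
            for pos0, base in enumerate(insert_part):
                pos = pos0 + 1
                if start <= pos <= end:
                    continue
                assert (
                    base.upper().replace("T", "U") == endo.residues[pos0]
                ), f"{name} disagrees at +{pos}"


class TestRegions:
    def test_composition_window_has_reported_counts(self, endo):
        table = composition(endo, tgfb1.COMPOSITION_WINDOW)
        assert table.counts == {"G": 36, "C": 36, "A": 4, "U": 4}
        assert table.gc_fraction == pytest.approx(0.9)

    def test_extract_full_range_is_identity(self, endo):
        sub = extract_region(endo, endo.start, endo.end)
        assert sub.residues == endo.residues

    def test_extract_stem_loop_matches_string_slice(self, endo):
        sub = extract_region(endo, 77, 106)
        assert len(sub) == 30
        assert sub.residues == endo.residues[76:106]
        assert sub.offset == 77

    def test_out_of_range_reports_valid_interval(self, endo):
        with pytest.raises(BoundsError, match="1..167"):
            extract_region(endo, 100, 200)

    def test_homogeneous_composition(self):
        table = composition(SequenceRecord("g", "GGGG"))
        assert table.counts["G"] == 4 and table.gc_fraction == 1.0

    @settings(max_examples=25, derandomize=True)
    @given(rna_text)
    def test_composition_matches_per_character_tally(self, residues):
        rec = SequenceRecord("x", residues)
        table = composition(rec)
        for base in "ACGU":
            assert table.counts[base] == residues.count(base)
        assert sum(table.counts.values()) == len(residues)


class TestSubstitution:
    @pytest.mark.parametrize("name", sorted(tgfb1.MUTANT_REGIONS))
    def test_substitution_reproduces_each_table_assembly(self, endo, mutant_records, name):
        start, end = tgfb1.MUTANT_REGIONS[name]
        built = apply_substitution(endo, start, end, "A")
        assert built.residues == mutant_records[name].residues

    def test_substituting_existing_residue_is_a_noop(self, endo):
        pos = endo.residues.index("G") + 1
        assert apply_substitution(endo, pos, pos, "G").residues == endo.residues

    def test_construct_naming_convention(self, endo):
        assert apply_substitution(endo, 50, 56, "A").id == f"{endo.id}-50/56A"
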