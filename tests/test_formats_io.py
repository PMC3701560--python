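"""I/O contracts: FASTA, alignments, TSV tables, run config."""

import pytest
from hypothesis import given, settings, strategies as st

from zfscan.formats_io import (
    AMINO_ACIDS,
    FamilyAlignment,
    FormatError,
    MasterList,
    PipelineConfig,
    SequenceRecord,
    Taxonomy,
    read_alignment,
    read_fasta,
    read_master_list,
    read_taxonomy,
    write_alignment,
    write_fasta,
    write_master_list,
    write_taxonomy,
)


class TestFasta:
    def test_parses_entries_with_accession_and_uppercasing(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">acc1 some description\nmkvl\n>acc2\nACDE*\n")
        recs = read_fasta(p, species_id="sp")
        assert [r.accession for r in recs] == ["acc1", "acc2"]
        assert recs[0].residues == "MKVL"  # upper-cased
        assert recs[1].residues == "ACDE"  # stop symbol stripped
        assert all(r.species_id == "sp" for r in recs)

    def test_duplicate_accession_is_named_in_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nMK\n>x\nML\n")
        with pytest.raises(FormatError, match="'x'"):
            read_fasta(p)

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nMK\n>y\n\n")
        with pytest.raises(FormatError, match="empty"):
            read_fasta(p)

    def test_residues_outside_alphabet_raise(self):
        with pytest.raises(FormatError, match="alphabet"):
            SequenceRecord(accession="a", residues="MK1")

    @settings(derandomize=True, max_examples=30)
    @given(
        entries=st.lists(
            st.tuples(
                st.integers(0, 10**6),
                st.text(alphabet=AMINO_ACIDS + "X", min_size=1, max_size=200),
            ),
            min_size=1,
            max_size=8,
            unique_by=lambda t: t[0],
        )
    )
    def test_fasta_round_trip_is_byte_stable(self, tmp_path_factory, entries):
        tmp = tmp_path_factory.mktemp("rt")
        recs = [SequenceRecord(f"acc{i}", res) for i, res in entries]
        write_fasta(recs, tmp / "x.fasta")
        back = read_fasta(tmp / "x.fasta")
        assert [(r.accession, r.residues) for r in back] == [
            (r.accession, r.residues) for r in recs
        ]
        write_fasta(back, tmp / "y.fasta")
        assert (tmp / "x.fasta").read_bytes() == (tmp / "y.fasta").read_bytes()


class TestAlignment:
    def test_reads_gapped_fasta(self, tmp_path):
        p = tmp_path / "FAM9.fasta"
        p.write_text(">r1\nAC-DEFGHIK\n>r2\nACCDEFGHIK\n>r3\nAC-DEFGH-K\n")
        aln = read_alignment(p, "fasta")
        assert aln.family_id == "FAM9"
        assert aln.width == 10 and len(aln.rows) == 3

    def test_ragged_rows_error_names_offender(self, tmp_path):
        p = tmp_path / "f.fasta"
        p.write_text(">r1\nACDEFGHIKL\n>r2\nACDEFGHIK\n")
        with pytest.raises(FormatError, match="r2"):
            read_alignment(p, "fasta")

    def test_stockholm_rf_line_becomes_match_mask(self, tmp_path):
        p = tmp_path / "f.sto"
        p.write_text(
            "# STOCKHOLM 1.0\n"
            "r1 AC-D\n"
            "r2 ACCD\n"
            "#=GC RF xx.x\n"
            "//\n"
        )
        aln = read_alignment(p, "stockholm")
        assert aln.rf_mask == (True, True, False, True)

    def test_alignment_round_trip(self, tmp_path):
        aln = FamilyAlignment("f", (("r1", "AC-D"), ("r2", "ACCD")))
        write_alignment(aln, tmp_path / "f.fasta")
        back = read_alignment(tmp_path / "f.fasta", "fasta", family_id="f")
        assert back.rows == aln.rows

    def test_gap_free_invariant_on_sequence_records(self):
        with pytest.raises(FormatError):
            SequenceRecord(accession="a", residues="AC-D")


class TestMasterList:
    def test_two_families_three_members_each(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "family_id\taccession\n"
            + "".join(f"F{f}\ta{f}{i}\n" for f in (1, 2) for i in range(3))
        )
        m = read_master_list(p)
        assert set(m.families) == {"F1", "F2"}
        assert all(len(m[f]) == 3 for f in m.families)

    def test_accession_in_two_families_is_ambiguous(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("F1\tshared\nF2\tshared\n")
        with pytest.raises(FormatError, match="shared"):
            read_master_list(p)

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        p = tmp_path / "m.tsv"
        p.write_text("")
        with caplog.at_level("WARNING"):
            m = read_master_list(p)
        assert m.families == {}
        assert any("empty" in r.message for r in caplog.records)

    def test_round_trip(self, tmp_path):
        m = MasterList({"F1": frozenset({"a", "b"}), "F2": frozenset({"c"})})
        write_master_list(m, tmp_path / "m.tsv")
        assert read_master_list(tmp_path / "m.tsv").families == m.families


class TestTaxonomy:
    def test_reads_explicit_group_order(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "#group_order=protist,metazoan\n"
            "species_id\tphylum_class\tgroup\n"
            "s1\tP1\tmetazoan\n"
            "s2\tP2\tprotist\n"
        )
        t = read_taxonomy(p)
        assert t.group_order == ("protist", "metazoan")
        assert t.group_of("s1") == "metazoan"
        assert t.phylum_of("s2") == "P2"

    def test_round_trip(self, tmp_path):
        t = Taxonomy({"s1": ("P1", "g1"), "s2": ("P2", "g2")}, ("g2", "g1"))
        write_taxonomy(t, tmp_path / "t.tsv")
        assert read_taxonomy(tmp_path / "t.tsv") == t

    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("s1\tP1\tg\ns1\tP1\tg\n")
        with pytest.raises(FormatError, match="twice"):
            read_taxonomy(p)

    def test_group_not_in_order_rejected(self):
        with pytest.raises(FormatError):
            Taxonomy({"s1": ("P1", "g1")}, ("g2",))


class TestPipelineConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(evalue_threshold=0.01, total_rounds=2, rng_seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert PipelineConfig.from_yaml(tmp_path / "c.yaml") == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("no_such_option: 1\n")
        with pytest.raises(FormatError, match="no_such_option"):
            PipelineConfig.from_yaml(tmp_path / "c.yaml")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"evalue_threshold": 0.0},
            {"total_rounds": 0},
            {"hole_majority": 1.5},
            {"pseudocount_alpha": -1.0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PipelineConfig(**kwargs)
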