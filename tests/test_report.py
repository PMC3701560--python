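"""Presence matrix, block detection, hole/loner flags, duplicate collapsing."""

import numpy as np
import pytest

from zfscan.formats_io import PipelineConfig, SequenceRecord, Taxonomy
from zfscan.pipeline import FamilyCallTable
from zfscan.report import (
    build_matrix,
    dedupe_paralogs,
    detect_blocks,
    flag_holes_loners,
    render_summary,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _tax():
    species = {}
    for i in range(1, 6):
        species[f"a{i}"] = ("PA", "basal")
    for i in range(1, 6):
        species[f"b{i}"] = ("PB", "derived")
    return Taxonomy(species, ("basal", "derived"))


def _calls(presence: dict[tuple[str, str], int], tax: Taxonomy) -> FamilyCallTable:
    """Build a call table from (species, family) -> member count."""
    rng = np.random.default_rng(0)
    fams = tuple(sorted({f for _, f in presence}))
    sps = tuple(sorted(tax.species))
    members = {}
    seqs: dict[str, str] = {}
    for (sp, fam), n in presence.items():
        if fam not in seqs:  # one distinct sequence per family
            seqs[fam] = "".join(rng.choice(list(AA), 80))
        recs = []
        for i in range(n):
            # distinct paralogs: mutate enough residues to stay below the
            # duplicate-identity threshold
            res = list(seqs[fam])
            for j in range(0, 80, 16):
                res[(j + 7 * i) % 80] = AA[(AA.index(res[(j + 7 * i) % 80]) + 1 + i) % 20]
            recs.append(SequenceRecord(f"{sp}_{fam}_m{i+1}", "".join(res), sp))
        if recs:
            members[(sp, fam)] = tuple(recs)
    status = {}
    for sp in sps:
        for fam in fams:
            n = len(members.get((sp, fam), ()))
            status[(sp, fam)] = f"present({n})" if n else "not_assessed"
    return FamilyCallTable(
        families=fams, species=sps, members=members, status=status,
        found_in_round={}, clade_tag={}, audit=(),
    )


class TestBuildMatrix:
    def test_counts_and_phylum_any_species_rule(self):
        tax = _tax()
        calls = _calls({("a1", "F"): 2, ("a2", "F"): 1}, tax)
        m = build_matrix(calls, tax)
        assert m.counts.loc["a1", "F"] == 2
        assert m.counts.loc["a3", "F"] == 0
        # phylum presence even though three species of PA lack the family
        assert bool(m.phylum_presence.loc["PA", "F"]) is True
        assert bool(m.phylum_presence.loc["PB", "F"]) is False

    def test_cell_sum_equals_total_nonduplicate_members(self):
        tax = _tax()
        calls = _calls({("a1", "F"): 2, ("b1", "F"): 1, ("b2", "G"): 3}, tax)
        m = build_matrix(calls, tax)
        assert m.counts.values.sum() == 6

    def test_unknown_species_rejected(self):
        tax = _tax()
        calls = _calls({("a1", "F"): 1}, tax)
        object.__setattr__  # (FamilyCallTable is mutable; adjust directly)
        calls.species = calls.species + ("ghost",)
        with pytest.raises(KeyError, match="ghost"):
            build_matrix(calls, tax)


class TestBlocks:
    def test_family_in_all_groups_gets_most_basal_block(self):
        tax = _tax()
        calls = _calls({("a1", "F"): 1, ("b1", "F"): 1}, tax)
        m = build_matrix(calls, tax)
        assert detect_blocks(m)["F"] == "basal"

    def test_family_only_in_derived_group(self):
        tax = _tax()
        calls = _calls({("b1", "F"): 1, ("b2", "F"): 1}, tax)
        m = build_matrix(calls, tax)
        assert detect_blocks(m)["F"] == "derived"

    def test_single_species_family_is_none(self):
        tax = _tax()
        calls = _calls({("b1", "F"): 2}, tax)  # two members, one species
        m = build_matrix(calls, tax)
        assert detect_blocks(m)["F"] == "none"

    def test_blocks_invariant_under_species_permutation_within_group(self):
        tax = _tax()
        calls = _calls({("a1", "F"): 1, ("b2", "F"): 1, ("b3", "G"): 1, ("b4", "G"): 1}, tax)
        m = build_matrix(calls, tax)
        before = dict(detect_blocks(m))
        perm = m.counts.copy()
        perm.loc[["b2", "b3"]] = perm.loc[["b3", "b2"]].values  # swap group peers
        m.counts = perm
        for phylum in m.phylum_presence.index:
            sps = [s for s in tax.species_in_phylum(phylum)]
            m.phylum_presence.loc[phylum] = (perm.loc[sps] >= 1).any(axis=0)
        assert detect_blocks(m) == before


class TestHolesAndLoners:
    def test_absence_among_present_peers_is_a_hole(self):
        tax = _tax()
        calls = _calls({(f"a{i}", "F"): 1 for i in (1, 2, 3, 4)}, tax)  # a5 lacks F
        m = build_matrix(calls, tax)
        holes, loners = flag_holes_loners(m, tax, PipelineConfig())
        assert ("a5", "F") in holes

    def test_small_phylum_never_yields_holes(self):
        species = {"x1": ("PX", "g"), "x2": ("PX", "g")}
        tax = Taxonomy(species, ("g",))
        calls = _calls({("x1", "F"): 1}, tax)
        m = build_matrix(calls, tax)
        holes, _ = flag_holes_loners(m, tax, PipelineConfig())
        assert holes == frozenset()

    def test_isolated_presence_in_large_group_is_a_loner(self):
        species = {f"s{i}": (f"P{i % 2}", "g") for i in range(10)}
        tax = Taxonomy(species, ("g",))
        calls = _calls({("s3", "F"): 1}, tax)
        m = build_matrix(calls, tax)
        _, loners = flag_holes_loners(m, tax, PipelineConfig())
        assert ("s3", "F") in loners

    def test_hole_and_loner_sets_are_disjoint(self, benchmark_runs):
        for seed, (sim, corpus, cfg, calls) in benchmark_runs.items():
            m = build_matrix(calls, corpus.taxonomy, cfg)
            holes, loners = flag_holes_loners(m, corpus.taxonomy, cfg)
            assert holes & loners == frozenset()


class TestDedupe:
    def test_identical_members_collapse_to_one(self):
        seq = "".join(np.random.default_rng(1).choice(list(AA), 100))
        a = SequenceRecord("m1", seq, "sp")
        b = SequenceRecord("m2", seq, "sp")
        retained, groups = dedupe_paralogs([b, a], PipelineConfig())
        assert [r.accession for r in retained] == ["m1"]
        assert groups == [("m1", "m2")]

    def test_diverged_paralogs_both_retained(self):
        rng = np.random.default_rng(2)
        seq = list(rng.choice(list(AA), 100))
        other = list(seq)
        for i in range(0, 100, 7):  # ~15% divergence
            other[i] = AA[(AA.index(other[i]) + 3) % 20]
        retained, groups = dedupe_paralogs(
            [SequenceRecord("m1", "".join(seq), "sp"),
             SequenceRecord("m2", "".join(other), "sp")],
            PipelineConfig(),
        )
        assert len(retained) == 2 and groups == []

    def test_single_member_unchanged(self):
        rec = SequenceRecord("m1", "MKWVMKWVMKWV", "sp")
        retained, groups = dedupe_paralogs([rec], PipelineConfig())
        assert retained == [rec] and groups == []

    def test_collapsing_duplicates_preserves_phylum_presence(self):
        tax = _tax()
        seq = "".join(np.random.default_rng(3).choice(list(AA), 90))
        recs = tuple(
            SequenceRecord(f"a1_F_m{i}", seq, "a1") for i in range(1, 4)
        )  # three byte-identical copies
        calls = _calls({("a1", "F"): 1}, tax)
        calls.members[("a1", "F")] = recs
        m = build_matrix(calls, tax, PipelineConfig())
        assert m.counts.loc["a1", "F"] == 1  # collapsed
        assert bool(m.phylum_presence.loc["PA", "F"]) is True


class TestRenderSummary:
    def test_one_row_per_phylum_one_column_per_family(self):
        tax = _tax()
        calls = _calls({("a1", "F"): 1, ("a2", "F"): 1, ("b1", "G"): 1, ("b2", "G"): 1}, tax)
        m = build_matrix(calls, tax)
        out = render_summary(m, "tsv")
        lines = out.strip().splitlines()
        header = lines[0].split("\t")
        assert header[3:] == ["F", "G"]
        assert {l.split("\t")[0] for l in lines[2:4]} == {"PA", "PB"}

    def test_rerun_is_byte_identical(self):
        tax = _tax()
        calls = _calls({("a1", "F"): 1, ("b3", "G"): 2}, tax)
        m = build_matrix(calls, tax)
        assert render_summary(m, "tsv") == render_summary(m, "tsv")
        assert render_summary(m, "markdown") == render_summary(m, "markdown")

    def test_empty_call_table_renders_header_only_with_warning(self, caplog):
        tax = _tax()
        calls = _calls({}, tax)
        calls.families = ("F",)
        m = build_matrix(calls, tax)
        with caplog.at_level("WARNING"):
            out = render_summary(m, "tsv")
        assert any("empty" in r.message for r in caplog.records)
        assert out.splitlines()[0].startswith("phylum_class")

    def test_unknown_format_rejected(self):
        tax = _tax()
        m = build_matrix(_calls({("a1", "F"): 1}, tax), tax)
        with pytest.raises(ValueError):
            render_summary(m, "xlsx")
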