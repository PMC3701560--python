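"""Profile construction, Viterbi scoring, and Gumbel calibration."""

import math

import numpy as np
import pytest
from scipy.stats import gumbel_r

from oracles import enumerate_viterbi
from zfscan.formats_io import FamilyAlignment, PipelineConfig
from zfscan.profile_hmm import (
    CalibrationError,
    HmmHit,
    ProfileHMM,
    assign_match_columns,
    build_profile,
    calibrate,
    evalue,
    fit_gumbel,
    load_profile,
    save_profile,
    viterbi_best_path,
    viterbi_score,
)


def toy_profile_m1(emit="A"):
    """M=1 profile emitting one residue with probability 1, uniform background."""
    em = np.zeros((1, 20))
    em[0, "ACDEFGHIKLMNPQRSTVWY".index(emit)] = 1.0
    bg = np.full(20, 0.05)
    return ProfileHMM(
        "toy", "general", 1, em, bg, bg,
        *(np.zeros(1) for _ in range(7)),
        entry=np.ones(1), exit=np.ones(1),
    )


class TestMatchColumns:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            # 0/3 gaps -> match; 2/3 gaps -> insert
            ((("a", "AC"), ("b", "A-"), ("c", "A-")), (True, False)),
            # exactly at the threshold (2/4) -> insert: rule is strict less-than
            ((("a", "AC"), ("b", "A-"), ("c", "AC"), ("d", "A-")), (True, False)),
        ],
    )
    def test_gap_fraction_rule(self, rows, expected):
        aln = FamilyAlignment("f", rows)
        assert assign_match_columns(aln, 0.5) == expected

    def test_rf_mask_overrides_gap_rule(self):
        aln = FamilyAlignment("f", (("a", "AC"), ("b", "AC")), rf_mask=(False, True))
        assert assign_match_columns(aln, 0.5) == (False, True)

    def test_all_insert_columns_is_an_error(self):
        aln = FamilyAlignment("f", (("a", "A-"), ("b", "-C"), ("c", "--"), ("d", "--")))
        with pytest.raises(ValueError, match="no match columns"):
            assign_match_columns(aln, 0.5)


class TestBuildProfile:
    def test_identical_rows_alpha_zero_gives_certain_emissions(self):
        aln = FamilyAlignment("f", (("a", "ACD"), ("b", "ACD"), ("c", "ACD")))
        hmm = build_profile(aln, PipelineConfig(pseudocount_alpha=0.0))
        assert hmm.M == 3
        for k, res in enumerate("ACD"):
            assert hmm.match_emissions[k]["ACDEFGHIKLMNPQRSTVWY".index(res)] == 1.0

    def test_laplace_pseudocount_closed_form(self):
        aln = FamilyAlignment("f", (("a", "ACD"), ("b", "ACD"), ("c", "ACD")))
        hmm = build_profile(aln, PipelineConfig(pseudocount_alpha=1.0))
        assert hmm.match_emissions[0][0] == pytest.approx(4 / 23)

    def test_all_gap_column_becomes_insert(self):
        aln = FamilyAlignment("f", (("a", "A-D"), ("b", "A-D"), ("c", "A-D")))
        hmm = build_profile(aln, PipelineConfig())
        assert hmm.M == 2

    def test_single_row_rejected(self):
        aln = FamilyAlignment("f", (("a", "ACD"),))
        with pytest.raises(ValueError, match=">= 2 rows"):
            build_profile(aln, PipelineConfig())

    def test_probability_rows_normalised(self):
        aln = FamilyAlignment(
            "f", (("a", "AC-DA"), ("b", "ACCDA"), ("c", "A--DA"), ("d", "CC-DC"))
        )
        hmm = build_profile(aln, PipelineConfig())
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.isclose(hmm.entry.sum(), 1.0, atol=1e-9)
        assert np.isclose(hmm.exit.sum(), 1.0, atol=1e-9)
        last = hmm.M - 1
        fans = [
            (hmm.tMM + hmm.tMI + hmm.tMD)[:last],
            (hmm.tIM + hmm.tII)[:last],
            (hmm.tDM + hmm.tDD)[1:last],
        ]
        for fan in fans:
            assert np.allclose(fan, 1.0, atol=1e-9)

    def test_adding_identical_row_leaves_emissions_unchanged(self):
        rows = (("a", "ACD"), ("b", "AAD"))
        cfg = PipelineConfig(pseudocount_alpha=0.0)
        h1 = build_profile(FamilyAlignment("f", rows), cfg)
        h2 = build_profile(FamilyAlignment("f", rows + (("c", "ACD"),)), cfg)
        # relative emission proportions shift but certainties are preserved:
        # the spec property is for duplicating the whole row set
        h3 = build_profile(FamilyAlignment("f", rows + tuple(
            (acc + "_copy", g) for acc, g in rows)), cfg)
        assert np.allclose(h1.match_emissions, h3.match_emissions)


class TestViterbi:
    def test_m1_single_path_closed_form(self):
        score, env, best = viterbi_score(toy_profile_m1(), "A")
        assert score == pytest.approx(math.log2(20))
        assert env == [(1, 1)] and best == score

    def test_oracle_equivalence_on_toy_profiles(self):
        import itertools

        aln = FamilyAlignment("f", (("a", "ACD"), ("b", "A-D"), ("c", "CCA")))
        hmm = build_profile(aln, PipelineConfig())
        for tup in itertools.product("ACD", repeat=4):
            seq = "".join(tup)
            impl, _, _ = viterbi_best_path(hmm, seq)
            assert impl == pytest.approx(enumerate_viterbi(hmm, seq), abs=1e-9)

    def test_consensus_beats_its_shuffles(self):
        rng = np.random.default_rng(11)
        consensus = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40))
        rows = tuple((f"r{i}", consensus) for i in range(3))
        hmm = build_profile(FamilyAlignment("f", rows), PipelineConfig())
        ref, _, _ = viterbi_score(hmm, consensus)
        for _ in range(100):
            shuf = "".join(rng.permutation(list(consensus)))
            s, _, _ = viterbi_score(hmm, shuf)
            assert s <= ref

    def test_reversed_consensus_scores_strictly_lower(self):
        consensus = "ACDEFGHIKLMNPQRSTVWY"
        rows = tuple((f"r{i}", consensus) for i in range(3))
        hmm = build_profile(FamilyAlignment("f", rows), PipelineConfig())
        fwd, _, _ = viterbi_score(hmm, consensus)
        rev, _, _ = viterbi_score(hmm, consensus[::-1])
        assert rev < fwd

    def test_x_residue_scores_as_background(self):
        score, _, _ = viterbi_score(toy_profile_m1(), "X")
        # emission odds zero: only entry and exit costs remain (both log2(1)=0)
        assert score == pytest.approx(0.0)

    def test_two_copies_give_two_domains(self):
        consensus = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        rows = tuple((f"r{i}", consensus) for i in range(3))
        hmm = build_profile(FamilyAlignment("f", rows), PipelineConfig())
        single, env1, _ = viterbi_score(hmm, consensus)
        full, env2, best = viterbi_score(hmm, consensus + "GGGG" + consensus)
        assert len(env2) == 2
        assert full > single
        assert best <= full

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            viterbi_score(toy_profile_m1(), "")

    def test_residue_outside_alphabet_rejected(self):
        with pytest.raises(ValueError):
            viterbi_score(toy_profile_m1(), "AB")  # B not in the 20+X alphabet


class TestCalibration:
    def test_moments_fit_recovers_known_parameters(self):
        lam_true = 0.693
        draws = gumbel_r.rvs(loc=2.0, scale=1 / lam_true, size=10000, random_state=5)
        mu, lam = fit_gumbel(draws)
        assert lam == pytest.approx(lam_true, rel=0.05)
        assert mu == pytest.approx(2.0, abs=0.1)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(CalibrationError):
            fit_gumbel(np.full(500, 3.0))

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError):
            calibrate(toy_profile_m1(), n_shuffles=50)

    def test_evalue_closed_form_and_properties(self):
        hmm = calibrate(toy_profile_m1(), n_shuffles=200, seed=3, length=50)
        mu = hmm.calibration.mu
        assert evalue(hmm, mu, 1) == pytest.approx(1 - math.exp(-1), rel=1e-6)
        assert evalue(hmm, 5.0, 0) == 0.0
        assert evalue(hmm, 5.0, 20) == pytest.approx(2 * evalue(hmm, 5.0, 10))
        # strictly decreasing in score, vanishing in the limit
        scores = np.linspace(mu - 2, mu + 20, 40)
        evs = [evalue(hmm, s, 100) for s in scores]
        assert all(a > b for a, b in zip(evs, evs[1:]))
        assert evalue(hmm, 1e4, 100) == 0.0

    def test_uncalibrated_profile_has_no_evalue(self):
        with pytest.raises(CalibrationError):
            evalue(toy_profile_m1(), 10.0, 100)

    def test_calibration_reproducible_for_fixed_seed(self):
        h1 = calibrate(toy_profile_m1(), n_shuffles=150, seed=9, length=40)
        h2 = calibrate(toy_profile_m1(), n_shuffles=150, seed=9, length=40)
        assert h1.calibration == h2.calibration


class TestSerialization:
    def test_profile_text_round_trip(self, tmp_path):
        rng = np.random.default_rng(21)
        cons = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30))
        rows = (("a", cons), ("b", cons[:12] + "-" + cons[13:]), ("c", cons))
        aln = FamilyAlignment("fam7", rows)
        hmm = calibrate(build_profile(aln, PipelineConfig()), 150, seed=2, length=30)
        save_profile(hmm, tmp_path / "p.txt")
        back = load_profile(tmp_path / "p.txt")
        assert back.family_id == "fam7" and back.M == hmm.M
        assert np.allclose(back.match_emissions, hmm.match_emissions)
        assert np.allclose(back.tMM, hmm.tMM)
        assert back.calibration.mu == pytest.approx(hmm.calibration.mu, rel=1e-9)
        assert back.calibration.lam == pytest.approx(hmm.calibration.lam, rel=1e-9)
        assert (back.calibration.n, back.calibration.seed, back.calibration.length) == (
            hmm.calibration.n, hmm.calibration.seed, hmm.calibration.length,
        )
        # scores agree through the round trip
        s1, _, _ = viterbi_score(hmm, cons + "ACDACD")
        s2, _, _ = viterbi_score(back, cons + "ACDACD")
        assert s1 == pytest.approx(s2)


class TestHmmHit:
    def test_envelope_and_score_invariants_enforced(self):
        with pytest.raises(ValueError):
            HmmHit("f", "g", "s", "a", 10.0, 11.0, 0.1, ((1, 5),))
        with pytest.raises(ValueError):
            HmmHit("f", "g", "s", "a", 10.0, 5.0, 0.1, ((3, 5), (4, 8)))
        with pytest.raises(ValueError):
            HmmHit("f", "g", "s", "a", 10.0, 5.0, -0.1, ((1, 2),))
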