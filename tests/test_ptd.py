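"""Profile construction (closed-form oracle), information content, GPY/F
anchoring, PTD group classification and the RT clade screen."""

import math
import random

import pytest

from centroscan import panels
from centroscan.ptd import (
    AMINO_ACIDS, Profile, assign_clade, build_profile, classify_ptd,
    locate_gpyf, profile_information,
)

UNIFORM_BG = {a: 0.05 for a in AMINO_ACIDS}


def closed_form_score(count: int, total: int, pc: float, bg: float) -> float:
    """Independent oracle for one profile cell."""
    return math.log2(((count + pc * bg) / (total + pc)) / bg)


class TestBuildProfile:
    def test_cell_scores_match_closed_form(self):
        prof = build_profile(["ACD", "ACD"], pseudocount=1.0, background=UNIFORM_BG)
        for pos, observed in enumerate("ACD"):
            for aa in AMINO_ACIDS:
                expected = closed_form_score(
                    2 if aa == observed else 0, 2, 1.0, 0.05)
                assert prof.position_scores[pos][aa] == pytest.approx(expected)

    def test_fully_mixed_column_scores_zero(self):
        # one sequence per residue: every frequency equals the background
        seqs = [a for a in AMINO_ACIDS]
        prof = build_profile(seqs, pseudocount=1.0, background=UNIFORM_BG)
        for aa in AMINO_ACIDS:
            assert prof.position_scores[0][aa] == pytest.approx(0.0)

    def test_majority_gap_column_dropped(self):
        prof = build_profile(["-A", "-A", "-A", "AA"], pseudocount=0.5)
        assert prof.n_positions == 1

    def test_ragged_and_single_sequence_errors(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile(["AC", "ACD"])
        with pytest.raises(ValueError):
            build_profile(["ACD"])

    def test_gibbs_inequality_per_position(self):
        prof = panels.default_cr_profile()
        for pos in prof.position_scores:
            mean = sum(prof.background[a] * pos[a] for a in AMINO_ACIDS)
            assert mean <= 1e-9

    def test_save_load_round_trip(self, tmp_path):
        prof = build_profile(["ACDW", "ACDW", "ACEW"], pseudocount=0.5)
        p = tmp_path / "p.json"
        prof.save(p)
        back = Profile.load(p)
        assert back.scan("XACDWX") == prof.scan("XACDWX")


class TestInformation:
    def _profile_with_freqs(self, freqs):
        scores = [{a: 0.0 for a in AMINO_ACIDS} for _ in freqs]
        return Profile("t", scores, freqs, UNIFORM_BG, 0.0, 0.0)

    def test_uniform_position_is_zero_bits(self):
        prof = self._profile_with_freqs([dict(UNIFORM_BG)])
        bits, total = profile_information(prof)
        assert bits[0] == pytest.approx(0.0, abs=1e-12)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_single_residue_position_is_log2_20(self):
        freqs = {a: (1.0 if a == "W" else 0.0) for a in AMINO_ACIDS}
        bits, _ = profile_information(self._profile_with_freqs([freqs]))
        assert bits[0] == pytest.approx(math.log2(20))

    def test_half_half_position(self):
        freqs = {a: 0.0 for a in AMINO_ACIDS}
        freqs["A"] = freqs["W"] = 0.5
        bits, _ = profile_information(self._profile_with_freqs([freqs]))
        assert bits[0] == pytest.approx(math.log2(20) - 1.0)

    def test_total_bounded(self):
        prof = panels.default_chd2_profile()
        bits, total = profile_information(prof)
        assert 0 <= total <= prof.n_positions * math.log2(20)
        assert all(b >= -1e-9 for b in bits)


class TestGpyf:
    @pytest.mark.parametrize("tail,expected", [
        ("MAKGPYLL", 3),
        ("MAKGPFLL", 3),
        ("AAAA", None),
        ("GPYGPF", 0),
    ])
    def test_first_occurrence(self, tail, expected):
        assert locate_gpyf(tail) == expected

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            locate_gpyf("")


@pytest.fixture(scope="module")
def profiles():
    return panels.default_cr_profile(), panels.default_chd2_profile()


@pytest.fixture(scope="module")
def rt_panels():
    return panels.rt_reference_panels()


class TestClassifyPtd:
    def test_cr_consensus_is_group_a(self, profiles):
        cr, chd2 = profiles
        tail = "DSSAKGPY" + panels.CR_CONSENSUS + "LE"
        call = classify_ptd(tail, cr, chd2)
        assert (call.ptd_type, call.group) == ("CR_MOTIF", "A")
        assert call.cr_score >= cr.score_threshold
        # oracle: the consensus window score equals the direct window score
        assert call.cr_score >= cr.window_score(panels.CR_CONSENSUS) - 1e-9

    def test_short_bare_tail_is_group_b(self, profiles):
        cr, chd2 = profiles
        call = classify_ptd("DSSAKGPYLWDNRTQSIE", cr, chd2)
        assert (call.ptd_type, call.group) == ("NONE", "B")
        assert call.tail_length_aa <= 40
        assert not call.warnings

    def test_chd2_consensus_is_group_c(self, profiles):
        cr, chd2 = profiles
        tail = "DSSAKGPF" + panels.CHD2_CONSENSUS
        call = classify_ptd(tail, cr, chd2)
        assert (call.ptd_type, call.group) == ("CHROMODOMAIN_II", "C")

    def test_long_tail_without_hit_warns(self, profiles):
        cr, chd2 = profiles
        rng = random.Random(4)
        junk = "".join(rng.choice("LIVSTQNDE") for _ in range(120))
        call = classify_ptd("DSSAKGPY" + junk, cr, chd2)
        assert call.group == "B"
        assert any("low" in w or "bound" in w for w in call.warnings)

    def test_missing_anchor_still_classifies_with_warning(self, profiles):
        cr, chd2 = profiles
        call = classify_ptd("M" + panels.CR_CONSENSUS, cr, chd2)
        assert call.group == "A"
        assert call.gpyf_position is None
        assert any("GPY" in w for w in call.warnings)

    def test_benchmark_accuracy_at_zero_divergence(self, profiles):
        """Consensus-tail classification on all three architectures is
        perfect when no divergence is applied."""
        cr, chd2 = profiles
        cases = {
            "A": "DSSAKGPY" + panels.CR_CONSENSUS,
            "B": "DSSAKGPY" + panels.TAIL_B_CONSENSUS,
            "C": "DSSAKGPY" + panels.CHD2_CONSENSUS,
        }
        for group, tail in cases.items():
            assert classify_ptd(tail, cr, chd2).group == group

    def test_benchmark_accuracy_under_divergence(self, profiles):
        """>= 90% group accuracy at ~5% protein divergence."""
        cr, chd2 = profiles
        rng = random.Random(2024)
        correct = total = 0
        for group, tail_seq in [("A", panels.CR_CONSENSUS),
                                ("C", panels.CHD2_CONSENSUS),
                                ("B", panels.TAIL_B_CONSENSUS)]:
            for _ in range(10):
                mutated = panels.mutate_protein(tail_seq, 0.05, rng)
                call = classify_ptd("DSSAKGPY" + mutated, cr, chd2)
                total += 1
                correct += call.group == group
        assert correct / total >= 0.9


class TestAssignClade:
    def test_self_hits(self, rt_panels):
        crm_rt = rt_panels["CRM"][0][1]
        clade, margin = assign_clade(crm_rt, rt_panels)
        assert clade == "CRM" and margin > 0
        tekay_rt = rt_panels["Tekay"][0][1]
        clade, margin = assign_clade(tekay_rt, rt_panels)
        assert clade == "Tekay" and margin > 0

    def test_mutated_crm_member_stays_crm(self, rt_panels):
        """Oracle: exhaustive pairwise score table recomputed independently."""
        from Bio.Align import PairwiseAligner, substitution_matrices

        rng = random.Random(88)
        query = panels.mutate_protein(rt_panels["CRM"][0][1], 0.05, rng)
        clade, margin = assign_clade(query, rt_panels)
        assert clade == "CRM" and margin > 0

        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score, aligner.extend_gap_score = -11, -1
        table = {
            c: max(aligner.score(query, s) for _, s in members)
            for c, members in rt_panels.items()
        }
        assert max(table, key=table.get) == "CRM"
        second = sorted(table.values())[-2]
        assert margin == pytest.approx(table["CRM"] - second)

    def test_invariant_to_panel_order_and_duplicates(self, rt_panels):
        query = rt_panels["Reina"][1][1]
        base = assign_clade(query, rt_panels)
        reordered = {k: list(reversed(v)) for k, v in reversed(list(rt_panels.items()))}
        duplicated = {k: v + v for k, v in rt_panels.items()}
        assert assign_clade(query, reordered) == base
        assert assign_clade(query, duplicated) == base

    def test_empty_query_is_error(self, rt_panels):
        with pytest.raises(ValueError):
            assign_clade("", rt_panels)
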