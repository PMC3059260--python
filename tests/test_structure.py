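"""Structural detectors: TSD, PBS, PPT, A-rich stretch, domain cassette."""

import random

import pytest

from centroscan import panels, simulate, structure
from centroscan._util import revcomp
from centroscan.ltr_detect import LTRCandidate
from centroscan.seqio import GenomicSequence
from centroscan.structure import StructureConfig


def _cand(seq_id, start, end, ltr_len, strand="+"):
    return LTRCandidate(
        seq_id=seq_id, strand=strand, start=start, end=end,
        ltr5_start=start, ltr5_end=start + ltr_len,
        ltr3_start=end - ltr_len, ltr3_end=end,
        ltr_identity=1.0, terminal_motif_score=10, detection_score=0.0,
    )


def _synthetic_locus(rng, internal, ltr_len=320, flank=50, tsd="ACGTA"):
    """flank + TSD + LTR + internal + LTR + TSD + flank, returning the
    genome and the candidate."""
    ltr = "TGATG" + "".join(rng.choice("ACGT") for _ in range(ltr_len - 10)) + "CATCA"
    left = "".join(rng.choice("ACGT") for _ in range(flank))
    right = "".join(rng.choice("ACGT") for _ in range(flank))
    residues = left + tsd + ltr + internal + ltr + tsd + right
    start = flank + len(tsd)
    end = start + 2 * len(ltr) + len(internal)
    return GenomicSequence("locus", residues), _cand("locus", start, end, len(ltr))


@pytest.fixture(scope="module")
def rng_m():
    return random.Random(99)


class TestTsd:
    def test_constructed_duplication(self, rng_m):
        genome, cand = _synthetic_locus(rng_m, "T" * 5000, tsd="ACGTA")
        tsd = structure.detect_tsd(genome, cand)
        assert tsd is not None
        assert tsd.sequence == "ACGTA"
        assert tsd.left[1] == cand.start and tsd.right[0] == cand.end

    def test_mismatched_flanks_give_none(self):
        rng = random.Random(3)
        genome, cand = _synthetic_locus(rng, "T" * 5000, tsd="ACGTA")
        # corrupt the right flank copy
        res = list(genome.residues)
        res[cand.end:cand.end + 5] = list("ACGTT")
        broken = GenomicSequence("locus", "".join(res))
        assert structure.detect_tsd(broken, cand) is None

    def test_element_at_sequence_edge_gives_none(self, rng_m):
        # only 2 bp of flank on each side: no room for a 5 bp duplication
        genome, cand = _synthetic_locus(rng_m, "T" * 5000, flank=2, tsd="")
        assert structure.detect_tsd(genome, cand) is None

    def test_simulated_default_tsd_length_is_5(self, pristine_benchmark):
        from centroscan.ltr_detect import find_ltr_pairs

        genome = pristine_benchmark.genome
        for cand in find_ltr_pairs(genome):
            tsd = structure.detect_tsd(genome, cand)
            assert tsd is not None and len(tsd.sequence) == 5


class TestPbs:
    def _internal_with_pbs(self, rng, pbs):
        return pbs + "G" + "".join(rng.choice("ACGT") for _ in range(4500))

    def test_constructed_14nt_match_at_offset_zero(self, rng_m):
        trna = panels.TRNA_MET_3PRIME
        pbs14 = revcomp(trna[-14:])
        genome, cand = _synthetic_locus(rng_m, self._internal_with_pbs(rng_m, pbs14))
        hit = structure.detect_pbs(genome, cand)
        assert hit is not None
        assert (hit.matched_len, hit.offset) == (14, 0)
        assert hit.start == cand.ltr5_end

    def test_10nt_complementarity_below_floor(self):
        rng = random.Random(5)
        trna = panels.TRNA_MET_3PRIME
        pbs10 = revcomp(trna[-10:])
        # follow with a base that cannot extend the match
        blocked = revcomp(trna[-11:])[-1]
        nxt = next(b for b in "ACGT" if b != blocked)
        internal = pbs10 + nxt + "".join(rng.choice("ACGT") for _ in range(4500))
        genome, cand = _synthetic_locus(rng, internal)
        assert structure.detect_pbs(genome, cand) is None

    def test_simulated_pbs_length_matches_manifest(self, pristine_benchmark):
        from centroscan.ltr_detect import find_ltr_pairs

        genome = pristine_benchmark.genome
        by_start = {t.start: t for t in pristine_benchmark.manifest.elements}
        for cand in find_ltr_pairs(genome):
            truth = by_start[cand.start]
            hit = structure.detect_pbs(genome, cand)
            assert hit is not None
            assert hit.matched_len == truth.pbs[1] - truth.pbs[0]
            assert (hit.start, hit.end) == truth.pbs


class TestPpt:
    def _with_window(self, rng, window):
        assert len(window) <= 40
        body = "".join(rng.choice("ACGT") for _ in range(4500))
        return body + window

    def test_constructed_run(self, rng_m):
        internal = self._with_window(rng_m, "CCTAAGGGGAGGGTC")
        genome, cand = _synthetic_locus(rng_m, internal)
        hit = structure.detect_ppt(genome, cand)
        assert hit is not None
        assert hit.sequence == "AAGGGGAGGG"
        assert hit.end == cand.ltr3_start - 2

    def test_no_qualifying_run_gives_none(self):
        rng = random.Random(8)
        window = ("CAT" * 14)[:40]  # purine runs of length <= 1
        internal = "".join(rng.choice("CT") for _ in range(4500)) + window
        genome, cand = _synthetic_locus(rng, internal)
        assert structure.detect_ppt(genome, cand) is None

    def test_tie_broken_toward_ltr(self, rng_m):
        window = "TTAAGGGTTTTTTAGAGATTT"  # two 5-purine runs
        internal = "".join(rng_m.choice("CT") for _ in range(4500)) + window
        genome, cand = _synthetic_locus(rng_m, internal)
        hit = structure.detect_ppt(genome, cand)
        assert hit.sequence == "AGAGA"

    def test_output_is_purine_only(self, small_benchmark):
        from centroscan.ltr_detect import find_ltr_pairs

        genome = small_benchmark.genome
        for cand in find_ltr_pairs(genome):
            hit = structure.detect_ppt(genome, cand)
            if hit:
                assert set(hit.sequence) <= set("AG")


class TestARich:
    def test_poly_a_stretch_found(self, rng_m):
        internal = ("GC" * 100) + "A" * 30 + ("GC" * 2200)
        genome, cand = _synthetic_locus(rng_m, internal)
        hit = structure.detect_a_rich(genome, cand)
        assert hit is not None
        assert hit.end - hit.start >= 30
        assert hit.a_fraction >= 0.99

    def test_uniform_composition_gives_none(self):
        internal = "ACGT" * 1200
        genome, cand = _synthetic_locus(random.Random(2), internal)
        assert structure.detect_a_rich(genome, cand) is None

    def test_simulated_a_rich_overlaps_manifest(self, pristine_benchmark):
        from centroscan.ltr_detect import find_ltr_pairs

        genome = pristine_benchmark.genome
        by_start = {t.start: t for t in pristine_benchmark.manifest.elements}
        seen = 0
        for cand in find_ltr_pairs(genome):
            truth = by_start[cand.start]
            if truth.a_rich is None:
                continue
            seen += 1
            hit = structure.detect_a_rich(genome, cand)
            assert hit is not None
            assert hit.start < truth.a_rich[1] and truth.a_rich[0] < hit.end
        assert seen >= 1  # fixture contains at least one A-rich element


class TestDomains:
    def test_intact_element_has_ordered_cassette(self, pristine_benchmark, domain_profiles):
        from centroscan.ltr_detect import find_ltr_pairs

        genome = pristine_benchmark.genome
        cand = find_ltr_pairs(genome)[0]
        ann = structure.annotate_domains(genome, cand, domain_profiles)
        assert [h.domain for h in sorted(ann.hits, key=lambda h: h.start)] == \
            ["GAG", "PRO", "RT", "RH", "INT"]
        assert ann.intact_orf

    def test_induced_stop_counts_as_disruption(self, pristine_benchmark, domain_profiles):
        from centroscan.ltr_detect import find_ltr_pairs

        genome = pristine_benchmark.genome
        cand = find_ltr_pairs(genome)[0]
        truth = next(t for t in pristine_benchmark.manifest.elements
                     if t.start == cand.start)
        rt_start, rt_end = truth.domains["RT"]
        mid = rt_start + 3 * ((rt_end - rt_start) // 6)
        res = list(genome.residues)
        res[mid:mid + 3] = list("TAA")  # in-frame stop inside RT
        mutated = GenomicSequence(genome.id, "".join(res))
        ann = structure.annotate_domains(mutated, cand, domain_profiles)
        rt_hit = next((h for h in ann.hits if h.domain == "RT"), None)
        assert rt_hit is None or rt_hit.disruptions >= 1
        assert not ann.intact_orf

    def test_group_a_codes_into_3ltr_group_c_does_not(self, pristine_benchmark, domain_profiles):
        from centroscan.ltr_detect import find_ltr_pairs

        genome = pristine_benchmark.genome
        by_start = {t.start: t for t in pristine_benchmark.manifest.elements}
        flags = {}
        for cand in find_ltr_pairs(genome):
            truth = by_start[cand.start]
            ann = structure.annotate_domains(genome, cand, domain_profiles)
            flags.setdefault(truth.group, []).append(ann.coding_into_3ltr)
        assert all(flags["A"]) and flags["A"]
        for g in ("B", "C"):
            if g in flags:
                assert not any(flags[g])

    def test_missing_panel_is_an_error(self, pristine_benchmark, domain_profiles):
        from centroscan.ltr_detect import find_ltr_pairs

        genome = pristine_benchmark.genome
        cand = find_ltr_pairs(genome)[0]
        partial = {k: v for k, v in domain_profiles.items() if k != "RH"}
        with pytest.raises(ValueError, match="RH"):
            structure.annotate_domains(genome, cand, partial)


def test_config_validation():
    with pytest.raises(ValueError):
        StructureConfig(pbs_min_match=19)
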