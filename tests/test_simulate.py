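"""Generator contracts: determinism, architecture, aging calibration, and
the generator->annotator round trip."""

import hashlib
import random

import pytest

from centroscan import simulate
from centroscan._util import hamming
from centroscan.ltr_detect import find_ltr_pairs
from centroscan.simulate import SimConfig, generate_element, implant_elements


class TestGenerateElement:
    def test_age_zero_ltrs_identical(self, rng):
        cfg = SimConfig(age_years=0.0)
        seq, truth = generate_element(cfg, rng, group="A")
        l5 = seq[truth.ltr5[0]:truth.ltr5[1]]
        l3 = seq[truth.ltr3[0]:truth.ltr3[1]]
        assert l5 == l3
        assert l5.startswith("TGATG") and l5.endswith("CATCA")

    def test_group_a_ptd_overlaps_3ltr(self, rng):
        cfg = SimConfig(age_years=0.0)
        seq, truth = generate_element(cfg, rng, group="A")
        assert truth.ptd_interval is not None
        assert truth.ptd_interval[1] > truth.ltr3[0]

    def test_group_c_ptd_ends_before_3ltr(self, rng):
        cfg = SimConfig(age_years=0.0)
        seq, truth = generate_element(cfg, rng, group="C")
        assert truth.ptd_interval[1] < truth.ltr3[0]

    def test_same_seed_reproduces_output(self):
        cfg = SimConfig()
        s1, t1 = generate_element(cfg, random.Random(42), group="B")
        s2, t2 = generate_element(cfg, random.Random(42), group="B")
        assert s1 == s2
        assert t1 == t2

    def test_feature_geometry_is_consistent(self, rng):
        cfg = SimConfig(age_years=0.0)
        for group in "ABC":
            seq, t = generate_element(cfg, rng, group=group)
            lo, hi = cfg.element_len_range
            assert lo <= len(seq) <= hi + 600
            assert t.ltr5[1] <= t.pbs[0] < t.pbs[1] <= t.ppt[0] < t.ppt[1] <= t.ltr3[0] + 1
            assert seq[t.pbs[0]:t.pbs[1]] == t.pbs_seq
            assert set(t.ppt_seq) <= set("AG")
            order = [t.domains[d] for d in ("GAG", "PRO", "RT", "RH", "INT")]
            assert order == sorted(order)


class TestAging:
    def test_realized_divergence_matches_2_rate_age(self):
        """Mean LTR pair divergence over 200 replicates is 2 x rate x age
        within binomial sampling error."""
        cfg = SimConfig()
        rng = random.Random(77)
        age = 1.0e6
        expected = 2 * cfg.subst_rate * age
        n, length = 200, 1000
        total_diffs = 0
        for _ in range(n):
            ltr = "".join(rng.choice("ACGT") for _ in range(length))
            a, b = list(ltr), list(ltr)
            for copy in (a, b):
                simulate._mutate_interval(copy, 0, length, cfg.subst_rate * age,
                                          cfg.ti_tv_ratio, rng)
            total_diffs += hamming("".join(a), "".join(b))
        realized = total_diffs / (n * length)
        sigma = (expected / (n * length)) ** 0.5
        assert abs(realized - expected) < 5 * sigma


class TestImplant:
    def _elements(self, k, rng):
        cfg = SimConfig(age_years=0.0)
        return [generate_element(cfg, rng, group="B") for _ in range(k)]

    def test_tsd_flanks_identical(self, rng):
        genome, manifest = implant_elements(20000, self._elements(1, rng),
                                            tsd_len=5, rng=rng)
        t = manifest.elements[0]
        left = genome.residues[t.tsd_left[0]:t.tsd_left[1]]
        right = genome.residues[t.tsd_right[0]:t.tsd_right[1]]
        assert left == right == t.tsd_seq
        assert len(left) == 5

    def test_manifest_intervals_disjoint_and_sorted(self, rng):
        genome, manifest = implant_elements(40000, self._elements(2, rng),
                                            tsd_len=5, rng=rng)
        spans = [(t.start, t.end) for t in manifest.elements]
        assert spans == sorted(spans)
        assert spans[0][1] <= spans[1][0]
        for t in manifest.elements:
            assert genome.residues[t.start:t.start + 5] == "TGATG"
            assert genome.residues[t.end - 5:t.end] == "CATCA"

    def test_tsd_sequences_vary_across_implants(self):
        rng = random.Random(31)
        elements = self._elements(12, rng)
        genome, manifest = implant_elements(200000, elements, tsd_len=5, rng=rng)
        tsds = {t.tsd_seq for t in manifest.elements}
        assert len(tsds) > 1

    def test_overcrowded_host_is_an_error(self, rng):
        with pytest.raises(ValueError, match="host too small"):
            implant_elements(3000, self._elements(3, rng), tsd_len=5, rng=rng)


class TestBenchmark:
    def test_mixture_counts_match_config(self, small_benchmark):
        crm = [t for t in small_benchmark.manifest.elements if t.clade == "CRM"]
        decoys = [t for t in small_benchmark.manifest.elements if t.clade == "Tekay"]
        assert len(crm) == 6 and len(decoys) == 1
        groups = [t.group for t in crm]
        # weights 9/8/8 over 6 elements: every group present, near-balanced
        assert set(groups) == {"A", "B", "C"}
        assert max(groups.count(g) for g in "ABC") <= 3
        assert decoys[0].group == "C"

    def test_default_mixture_is_9_8_8(self):
        cfg = SimConfig(age_years=0.0)
        bench = simulate.generate_benchmark(cfg, seed=3, include_decoy=False)
        groups = [t.group for t in bench.manifest.elements]
        assert (groups.count("A"), groups.count("B"), groups.count("C")) == (9, 8, 8)

    def test_fixed_seed_checksum_stable(self):
        cfg = SimConfig(n_elements=3, age_years=(0.0, 5e5))
        digests = []
        for _ in range(2):
            b = simulate.generate_benchmark(cfg, seed=123)
            h = hashlib.sha256()
            h.update(b.genome.residues.encode())
            for t in b.manifest.elements:
                h.update(repr((t.start, t.end, t.group, t.family_id)).encode())
            for rid, s in b.reads:
                h.update(s.encode())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_family_members_share_ltr_similarity(self, small_benchmark):
        from centroscan.families import ltr_identity

        by_family = {}
        g = small_benchmark.genome.residues
        for t in small_benchmark.manifest.elements:
            by_family.setdefault(t.family_id, []).append(g[t.ltr5[0]:t.ltr5[1]])
        for members in by_family.values():
            if len(members) > 1:
                ident, cov = ltr_identity(members[0], members[1])
                assert ident >= 70.0 and cov >= 0.8


class TestRoundTrip:
    def test_pristine_elements_recovered_exactly(self, pristine_benchmark):
        """At age 0 / divergence 0 every structural feature is recovered
        exactly: boundaries, TSD, PBS, PPT."""
        from centroscan import structure

        genome = pristine_benchmark.genome
        by_start = {t.start: t for t in pristine_benchmark.manifest.elements}
        cands = find_ltr_pairs(genome)
        assert len(cands) == len(by_start)
        for cand in cands:
            truth = by_start[cand.start]
            assert (cand.start, cand.end) == (truth.start, truth.end)
            assert (cand.ltr5_start, cand.ltr5_end) == truth.ltr5
            assert (cand.ltr3_start, cand.ltr3_end) == truth.ltr3
            tsd = structure.detect_tsd(genome, cand)
            assert tsd.sequence == truth.tsd_seq
            pbs = structure.detect_pbs(genome, cand)
            assert (pbs.start, pbs.end) == truth.pbs
            ppt = structure.detect_ppt(genome, cand)
            assert (ppt.start, ppt.end) == truth.ppt
            assert ppt.sequence == truth.ppt_seq

    def test_aged_elements_boundaries_within_5bp(self):
        """At ~1 My, >= 90% of LTR boundaries land within +/- 5 bp."""
        cfg = SimConfig(n_elements=8, age_years=1.0e6)
        bench = simulate.generate_benchmark(cfg, seed=77, include_decoy=False)
        truths = sorted(bench.manifest.elements, key=lambda t: t.start)
        cands = find_ltr_pairs(bench.genome)
        hits = 0
        for truth in truths:
            close = [c for c in cands if abs(c.start - truth.start) <= 50]
            if close and abs(close[0].start - truth.start) <= 5 \
                    and abs(close[0].end - truth.end) <= 5:
                hits += 1
        assert hits / len(truths) >= 0.9
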