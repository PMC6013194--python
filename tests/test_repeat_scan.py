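"""Profile construction, repeat detection and subfamily classification."""

import itertools

import numpy as np
import pytest

from famcensus import repeat_scan as rs
from famcensus import synthetic_data as sd

AA = sd.AMINO_ACIDS


def random_protein(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AA), n))


class TestBuildProfile:
    def test_background_frequency_columns_score_zero(self):
        # 20 sequences, one of each residue per column -> frequencies equal
        # the uniform background -> log-odds 0 everywhere
        seqs = ["".join(AA[(i + j) % 20] for j in range(12)) for i in range(20)]
        prof = rs.build_profile(seqs, pseudocount=1e-9)
        assert np.allclose(prof.log_odds, 0.0, atol=1e-6)

    def test_identical_sequences_small_pseudocount_limit(self):
        seqs = ["ACDEFGHIKLMN"] * 5
        prof = rs.build_profile(seqs, pseudocount=1e-9)
        for j, a in enumerate("ACDEFGHIKLMN"):
            assert prof.log_odds[j, AA.index(a)] == pytest.approx(
                np.log2(1 / 0.05), abs=1e-4)

    def test_matrix_matches_direct_formula(self):
        seqs = ["ACDEFGHIKLMN", "ACDEFGHIKLMW", "ACDEFGHIKLYN"]
        pc, bg = 1.0, 0.05
        prof = rs.build_profile(seqs, pseudocount=pc)
        counts = np.zeros((12, 20))
        for s in seqs:
            for j, c in enumerate(s):
                counts[j, AA.index(c)] += 1
        expected = np.log2(((counts + pc * bg) / (3 + pc)) / bg)
        assert np.allclose(prof.log_odds, expected)

    def test_majority_gap_columns_dropped(self):
        seqs = ["A-CDEFGHIKLMN", "A-CDEFGHIKLMN", "AWCDEFGHIKLMN"]
        prof = rs.build_profile(seqs)
        assert prof.width == 12

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            rs.build_profile(["ACDEFGHIKLMN", "ACDEFGHIKLM"])

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError):
            rs.build_profile(["-" * 12, "-" * 12])


@pytest.fixture(scope="module")
def profile():
    aln = sd.generate_seed_alignment(seed=1)
    return rs.build_profile([s for _, s in aln])


class TestScanRepeats:
    def test_planted_repeat_found_at_exact_position(self, profile):
        w = profile.width
        prot = (random_protein(100, 1) + sd.MYB_REPEAT_CONSENSUS
                + random_protein(80, 2))
        hits = rs.scan_repeats(prot, profile, min_score=50.0,
                               min_partial_score=1e9)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (100, 100 + w)
        assert hits[0].completeness == 1.0

    def test_short_protein_gives_empty_result(self, profile):
        assert rs.scan_repeats("ACDEF", profile, 0.0, 0.0) == []

    def test_random_background_has_no_hits_at_auto_threshold(self, profile):
        prots = {f"r{i}": random_protein(300, 100 + i) for i in range(20)}
        ms, mp = rs.calibrate_thresholds(prots, profile, seed=1)
        for p in prots.values():
            assert rs.scan_repeats(p, profile, ms, mp) == []

    def test_greedy_matches_exhaustive_max_score_subset(self, profile):
        # <=200-residue protein with two planted repeats: greedy resolution
        # equals the exhaustive maximum-total-score non-overlapping subset
        w = profile.width
        prot = (random_protein(30, 3) + sd.MYB_REPEAT_CONSENSUS
                + random_protein(10, 4) + sd.MYB_REPEAT_CONSENSUS
                + random_protein(30, 5))
        assert len(prot) <= 200
        min_score = 10.0
        hits = rs.scan_repeats(prot, profile, min_score, 1e9)
        # independent candidate enumeration: every full window above threshold
        idx = np.array([AA.index(c) for c in prot])
        cands = []
        for p in range(len(prot) - w + 1):
            s = sum(profile.log_odds[j, idx[p + j]] for j in range(w))
            if s >= min_score:
                cands.append((p, p + w, s))
        assert len(cands) <= 16, "toy too dense for exhaustive oracle"
        best_total, best_set = -1.0, []
        for r in range(1, len(cands) + 1):
            for sub in itertools.combinations(cands, r):
                ok = all(a2 >= e1 or a1 >= e2
                         for (a1, e1, _), (a2, e2, _) in
                         itertools.combinations(sub, 2))
                total = sum(s for _, _, s in sub)
                if ok and total > best_total:
                    best_total, best_set = total, sorted(sub)
        got = sorted((h.start, h.end) for h in hits)
        assert got == [(a, b) for a, b, _ in best_set]
        assert sum(h.score for h in hits) == pytest.approx(best_total)

    def test_higher_scoring_overlap_survives(self, profile):
        w = profile.width
        prot = random_protein(20, 6) + sd.MYB_REPEAT_CONSENSUS + random_protein(20, 7)
        hits = rs.scan_repeats(prot, profile, min_score=-50.0,
                               min_partial_score=1e9)
        exact = [h for h in hits if h.start == 20]
        assert len(exact) == 1
        # any other reported hit must not overlap the planted one
        for h in hits:
            if h.start != 20:
                assert h.end <= 20 or h.start >= 20 + w

    def test_raising_min_score_never_increases_hits(self, profile):
        prot = (random_protein(40, 8) + sd.MYB_REPEAT_CONSENSUS
                + random_protein(40, 9))
        counts = [len(rs.scan_repeats(prot, profile, t, 1e9))
                  for t in (-100, -50, 0, 50, 100, 200)]
        assert counts == sorted(counts, reverse=True)


def hit(start, end, score=100.0, completeness=1.0):
    return rs.RepeatHit(start, end, score, completeness)


class TestClassifyArchitecture:
    @pytest.mark.parametrize("hits,expect", [
        ([hit(0, 52), hit(57, 109)], "R2R3"),                 # gap 5
        ([hit(0, 52)], "MYB_RELATED"),
        ([hit(0, 52), hit(57, 109), hit(115, 167)], "R1R2R3"),
        ([hit(0, 52), hit(55, 107), hit(110, 162), hit(165, 217)], "FOUR_R"),
        ([hit(10, 36, completeness=0.5)], "ATYPICAL"),
        ([], "NOT_MYB"),
    ])
    def test_rule_instantiation(self, hits, expect):
        assert rs.classify_architecture(hits, 300) == expect

    def test_wide_gap_splits_run(self):
        hits = [hit(0, 52), hit(100, 152)]  # gap 48 > 30
        assert rs.classify_architecture(hits, 300) == "MYB_RELATED"

    def test_more_than_four_repeats_clamps_with_warning(self):
        hits = [hit(i * 55, i * 55 + 52) for i in range(5)]
        with pytest.warns(UserWarning):
            assert rs.classify_architecture(hits, 300) == "FOUR_R"

    def test_near_complete_hit_counts_as_complete(self):
        assert rs.classify_architecture([hit(0, 50, completeness=0.96)],
                                        200) == "MYB_RELATED"


class TestCensus:
    def test_zero_noise_census_recovers_spec_counts(self):
        spec = sd.FamilySpec(
            counts_per_class={"1R": 5, "2R3R": 10, "3R": 2, "4R": 1,
                              "ATYPICAL": 3, "NONE": 20},
            substitution_rate=0.0, seed=2)
        b = sd.generate_proteome(spec)
        aln = sd.generate_seed_alignment(seed=2)
        prof = rs.build_profile([s for _, s in aln])
        cens, archs = rs.census(b.proteins, prof, rs.ScanParams(seed=2))
        assert cens.counts["MYB_RELATED"] == 5
        assert cens.counts["R2R3"] == 10
        assert cens.counts["R1R2R3"] == 2
        assert cens.counts["FOUR_R"] == 1
        assert cens.counts["ATYPICAL"] == 3
        assert cens.total == 21

    def test_census_invariant_to_record_order(self, study_bundle, study_profile):
        _, b = study_bundle
        sub = dict(list(b.proteins.items())[:40])
        rev = dict(reversed(list(sub.items())))
        c1, a1 = rs.census(sub, study_profile, rs.ScanParams(seed=1))
        c2, a2 = rs.census(rev, study_profile, rs.ScanParams(seed=1))
        assert c1.counts == c2.counts
        assert {k: v.subfamily for k, v in a1.items()} == \
               {k: v.subfamily for k, v in a2.items()}

    def test_counts_partition_hit_proteins(self, study_census):
        cens, archs = study_census
        with_hits = sum(1 for a in archs.values() if a.hits)
        assert cens.total == with_hits
        all_members = [m for k, v in cens.members.items() for m in v]
        assert len(all_members) == len(set(all_members)) == len(archs)

    def test_empty_proteome_gives_empty_census(self, study_profile):
        cens, archs = rs.census(
            {}, study_profile, rs.ScanParams(min_score=0.0,
                                             min_partial_score=0.0))
        assert cens.total == 0 and archs == {}
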