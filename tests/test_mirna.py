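"""miRNA discovery: matching, folding, metrics, screening, targets."""

import numpy as np
import pytest

from estkit import (
    MatureRef,
    Seq,
    assign_family,
    discover_mirnas,
    excise_precursors,
    fold,
    hairpin_metrics,
    match_known,
    pair_table,
    predict_targets,
    revcomp,
    score_site,
)
from estkit.mirna import MatureHit, hairpin_loops
from estkit.synthetic_data import gen_hairpin_est, gen_target_transcript

from _oracles import check_structure_valid, max_fold_score, structure_score
from conftest import random_dna

REF = MatureRef("ath-miR156a", "UGACAGAAGAGAGUGAGCAC")
RNA = np.array(list("ACGU"))


def random_rna(rng, n):
    return "".join(RNA[rng.integers(0, 4, size=n)])


class TestAssignFamily:
    @pytest.mark.parametrize("name,family", [
        ("ath-miR156a", "156"),
        ("ghr-miR2948-5p", "2948"),
        ("osa-miR399d.2", "399"),
        ("ghr-miR390a,c", "390"),
    ])
    def test_examples(self, name, family):
        assert assign_family(name) == family

    def test_unparseable_name_reports_it(self):
        with pytest.raises(ValueError, match="not-a-mirna"):
            assign_family("not-a-mirna")


class TestMatchKnown:
    def test_exact_window_plus_strand(self, rng):
        mat = REF.sequence.replace("U", "T")
        est = Seq("e", random_dna(rng, 50) + mat + random_dna(rng, 50))
        hits = [h for h in match_known([est], [REF]) if h.strand == "+"]
        assert hits and hits[0].offset == 50 and hits[0].mismatches == 0

    def test_revcomp_with_two_substitutions_minus_strand(self, rng):
        mat = REF.sequence.replace("U", "T")
        window = list(revcomp(mat))
        window[3] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[3]]
        window[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[10]]
        est = Seq("e", random_dna(rng, 40) + "".join(window) + random_dna(rng, 40))
        hits = [h for h in match_known([est], [REF]) if h.strand == "-"]
        assert hits and hits[0].mismatches == 2

    def test_five_mismatches_rejected(self, rng):
        mat = list(REF.sequence.replace("U", "T"))
        for p in (0, 4, 8, 12, 16):
            mat[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mat[p]]
        est = Seq("e", "GGCC" * 10 + "".join(mat) + "GGCC" * 10)
        hits = [h for h in match_known([est], [REF], max_mismatch=4)
                if h.mismatches <= 4 and h.offset == 40]
        assert hits == []

    def test_min_mismatch_hit_kept_per_strand(self, rng):
        mat = REF.sequence.replace("U", "T")
        noisy = list(mat)
        noisy[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[5]]
        est = Seq("e", "".join(noisy) + random_dna(rng, 30) + mat)
        hits = [h for h in match_known([est], [REF]) if h.strand == "+"]
        assert len(hits) == 1 and hits[0].mismatches == 0


class TestExcisePrecursors:
    def test_window_grid_lengths(self):
        seq = Seq("e", "ACGT" * 100)
        hit = MatureHit("e", 190, "+", REF, 0)
        windows = excise_precursors(seq, hit)
        lengths = {e - s for s, e, _ in windows}
        assert all(60 <= l <= 300 for l in lengths)
        assert min(lengths) == 60 and max(lengths) == 300

    def test_clipping_at_five_prime_end(self):
        seq = Seq("e", "ACGT" * 100)
        hit = MatureHit("e", 5, "+", REF, 0)
        windows = excise_precursors(seq, hit)
        assert all(s >= 0 for s, _, _ in windows)
        assert any(moff == 5 for _, _, moff in windows)  # upstream clipped to 5

    def test_candidate_count_matches_grid_combinatorics(self):
        seq = Seq("e", "A" * 1000)
        hit = MatureHit("e", 400, "+", REF, 0)
        steps = tuple(range(0, 281, 20))
        lm = len(REF.sequence)
        expect = {(400 - u, 400 + lm + d)
                  for u in steps for d in steps
                  if 60 <= lm + u + d <= 300}
        got = {(s, e) for s, e, _ in excise_precursors(seq, hit, steps)}
        assert got == expect


class TestFold:
    def test_no_pairs(self):
        assert fold("AAAAAAAAAA") == ("..........", 0.0)

    def test_triple_gc_hairpin(self):
        assert fold("GGGAAAACCC") == ("(((....)))", 9.0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            rna = random_rna(rng, int(rng.integers(10, 15)))
            structure, mfe = fold(rna)
            assert mfe == max_fold_score(rna)
            assert check_structure_valid(structure)
            assert structure_score(rna, structure) == mfe

    def test_structures_balanced_min_loop(self, rng):
        for _ in range(30):
            structure, _ = fold(random_rna(rng, 80))
            assert check_structure_valid(structure, min_loop=3)

    def test_mfei_invariant_under_reversal(self, rng):
        for _ in range(10):
            rna = random_rna(rng, 90)
            s1, m1 = fold(rna)
            s2, m2 = fold(rna[::-1])
            assert m1 == m2  # pair weights are symmetric

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            fold("ACGUXACGUACGU")


class TestHairpinMetrics:
    def test_formulas(self):
        prec = "G" * 25 + "C" * 25 + "A" * 50  # GC% = 50, len 100
        gc, amfe, mfei, _ = hairpin_metrics(prec, "." * 100, 40.0, (0, 20))
        assert gc == pytest.approx(50.0)
        assert amfe == pytest.approx(40.0)
        assert mfei == pytest.approx(0.8)

    def test_zero_mfe(self):
        gc, amfe, mfei, _ = hairpin_metrics("GCAU" * 25, "." * 100, 0.0, (0, 20))
        assert amfe == 0.0 and mfei == 0.0

    def test_zero_gc_rejected(self):
        with pytest.raises(ValueError):
            hairpin_metrics("AU" * 50, "." * 100, 10.0, (0, 20))

    def test_arm_assignment(self):
        prec = "GGGGGGGGGGAAAAACCCCCCCCCC"
        structure, mfe = fold(prec)
        *_, loc5 = hairpin_metrics(prec, structure, mfe, (0, 8))
        *_, loc3 = hairpin_metrics(prec, structure, mfe, (17, 25))
        assert loc5 == "5p" and loc3 == "3p"

    def test_straddling_mature_flagged(self):
        prec = "GGGGGGGGGGAAAAACCCCCCCCCC"
        structure, mfe = fold(prec)
        *_, loc = hairpin_metrics(prec, structure, mfe, (8, 17))
        assert loc == "loop"


class TestPipelineRecovery:
    @pytest.mark.parametrize("arm,strand", [
        ("5p", "+"), ("3p", "+"), ("5p", "-"), ("3p", "-"),
    ])
    def test_planted_hairpin_recovered(self, arm, strand):
        est, man = gen_hairpin_est(REF, arm=arm, strand=strand, seed=77)
        cands = discover_mirnas([est], [REF])
        matching = [c for c in cands
                    if c.strand == strand and c.location == arm
                    and c.mature_seq == REF.sequence]
        assert matching, f"planted {arm}/{strand} hairpin not recovered"
        c = matching[0]
        assert c.mismatches_vs_ref == 0
        assert 18 <= c.lm <= 24
        pt = pair_table(c.structure)
        paired = sum(1 for i in range(c.mature_start, c.mature_start + c.lm)
                     if pt[i] != -1)
        assert paired >= 14

    def test_ranking_prefers_higher_mfei_on_equal_mismatch(self):
        est, _ = gen_hairpin_est(REF, arm="5p", seed=78)
        cands = discover_mirnas([est], [REF])
        # one survivor per (source, family, strand); it carries the max MFEI
        # among same-mismatch windows by construction of the dedup rule
        keys = [(c.source_id, c.family, c.strand) for c in cands]
        assert len(keys) == len(set(keys))

    def test_mature_absent_no_candidates(self, rng):
        est = Seq("e", random_dna(rng, 300))
        hits = match_known([est], [REF], max_mismatch=2)
        if not hits:  # random sequence essentially never matches at <=2
            assert discover_mirnas([est], [REF], max_mismatch=2) == []


class TestTargetPrediction:
    def test_perfect_complement_scores_zero(self):
        tr, man = gen_target_transcript(REF, (), seed=30)
        sites = predict_targets([("m", REF.sequence)], [tr])
        truth = man.items[0]
        assert any(s.start == truth["start"] and s.score == 0.0 for s in sites)

    def test_single_wobble_outside_seed_scores_half(self):
        tr, man = gen_target_transcript(REF, [(15, "wobble")], seed=31)
        sites = [s for s in predict_targets([("m", REF.sequence)], [tr])
                 if s.start == man.items[0]["start"]]
        assert sites and sites[0].score == 0.5 and sites[0].gu_pairs == 1

    def test_seed_region_penalty_doubled(self):
        tr, man = gen_target_transcript(REF, [(5, "mismatch")], seed=32)
        sites = [s for s in predict_targets([("m", REF.sequence)], [tr])
                 if s.start == man.items[0]["start"]]
        assert sites and sites[0].score == 2.0  # 1.0 mismatch doubled in 2-13

    def test_mismatch_at_position_ten_rejected(self):
        win = list("".join(
            {"A": "U", "U": "A", "G": "C", "C": "G"}[c] for c in REF.sequence
        ))[::-1]
        lm = len(REF.sequence)
        # corrupt the base facing mature position 10 into a hard mismatch
        m10 = REF.sequence[9]
        bad = {"A": "A", "U": "U", "G": "G", "C": "C"}[m10]
        win[lm - 10] = bad
        assert score_site(REF.sequence, "".join(win)) is None

    def test_three_consecutive_mismatches_rejected(self):
        with pytest.raises(ValueError):
            gen_target_transcript(REF, [(15, "mismatch"), (16, "mismatch"),
                                        (17, "mismatch")], seed=33)

    def test_shuffled_control_yields_no_sites(self):
        tr, _ = gen_target_transcript(REF, (), seed=34)
        rng = np.random.default_rng(35)
        shuffled = "".join(rng.permutation(list(tr.residues)))
        sites = predict_targets([("m", REF.sequence)], [Seq("shuf", shuffled)])
        assert sites == []

    def test_planted_scores_reproduced(self):
        for seed, spec, expect in [
            (40, [(15, "wobble"), (17, "wobble")], 1.0),
            (41, [(1, "mismatch")], 1.0),        # position 1 not doubled
            (42, [(9, "wobble")], 1.0),          # wobble doubled in 2-13
        ]:
            tr, man = gen_target_transcript(REF, spec, seed=seed)
            sites = [s for s in predict_targets([("m", REF.sequence)], [tr])
                     if s.start == man.items[0]["start"]]
            assert sites and sites[0].score == expect == man.items[0]["expected_score"]


class TestStructureHelpers:
    def test_pair_table_roundtrip(self):
        pt = pair_table("((..((...))..))")
        assert pt[0] == 14 and pt[14] == 0 and pt[4] == 10

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            pair_table("((..)")

    def test_hairpin_loops_found(self):
        assert hairpin_loops("((...))") == [(1, 5)]
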