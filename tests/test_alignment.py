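"""Candidate alleles and the three-scenario STR alignment likelihoods."""
import numpy as np
import pytest

from mosaicstr.alignment import (agreement_score, align_nostutter,
                                 align_stutter_del, align_stutter_ins,
                                 assign_read_to_haplotype,
                                 build_candidate_alleles,
                                 read_allele_likelihood, refine_mutation)
from mosaicstr.stutter import StutterModel
from mosaicstr.types import Allele, ReadSegmentation


def seg(core, left="AACCGGTTAA", right="TTGGCCAATT", rid="r"):
    return ReadSegmentation(read_id=rid, str_start=len(left),
                            str_end=len(left) + len(core), str_seq=core,
                            left_flank_seq=left, right_flank_seq=right,
                            viterbi_log_likelihood=-1.0, method="hmm")


class TestCandidateAlleles:
    def test_reference_only_pool(self, cag_locus):
        segs = [seg("CAG" * 8, rid=f"r{i}") for i in range(10)]
        pool = build_candidate_alleles(segs, cag_locus, "AATTA", "GGCTT")
        assert len(pool) == 1
        assert pool[0].origin == "reference"
        assert pool[0].support == 10

    def test_supported_alternative_promoted(self, cag_locus):
        segs = [seg("CAG" * 8, rid=f"r{i}") for i in range(8)]
        segs += [seg("CAG" * 9, rid=f"a{i}") for i in range(3)]
        pool = build_candidate_alleles(segs, cag_locus, "AATTA", "GGCTT",
                                       min_support=2)
        assert len(pool) == 2
        assert pool[1].core_str_seq == "CAG" * 9
        assert pool[1].support == 3

    def test_singleton_not_promoted(self, cag_locus):
        segs = [seg("CAG" * 8, rid=f"r{i}") for i in range(5)]
        segs += [seg("CAG" * 7 + "CAT", rid="x")]
        pool = build_candidate_alleles(segs, cag_locus, "AATTA", "GGCTT",
                                       min_support=2)
        assert len(pool) == 1

    def test_partial_span_reads_excluded(self, cag_locus):
        segs = [ReadSegmentation("r", 0, 24, "CAG" * 8, "", "TTTTT",
                                 -1.0, "hmm")] * 5
        pool = build_candidate_alleles(segs, cag_locus, "AATTA", "GGCTT")
        assert len(pool) == 1  # only the reference

    def test_pads_are_5bp(self, cag_locus):
        with pytest.raises(ValueError):
            Allele(core_str_seq="CAG", left_pad_5bp="AAT", right_pad_5bp="GGCTT")


class TestAgreement:
    def test_match_mismatch_and_normalization(self):
        assert agreement_score("A", "A", 0.01) == pytest.approx(0.99)
        assert agreement_score("A", "C", 0.01) == pytest.approx(0.01 / 3)
        total = sum(agreement_score("A", b, 0.02) for b in "ACGT")
        assert total == pytest.approx(1.0)


class TestNoStutter:
    def test_identical_sequences(self, default_model):
        x = "AACAGCAGAA"
        assert align_nostutter(x, x, np.zeros(10), default_model) == \
            pytest.approx(0.98)

    def test_single_mismatch_factor(self, default_model):
        x = "AACAGCAGAA"
        y = "AACAGCAGAT"
        e = np.full(10, 0.03)
        expected = 0.98 * (0.97 ** 9) * 0.01
        assert align_nostutter(x, y, e, default_model) == pytest.approx(expected)

    def test_monotone_in_mismatches(self, default_model):
        x = "AAAAAAAAAA"
        e = np.full(10, 0.05)
        prev = align_nostutter(x, x, e, default_model)
        for k in range(1, 5):
            y = "C" * k + x[k:]
            cur = align_nostutter(x, y, e, default_model)
            assert cur < prev
            prev = cur

    def test_length_mismatch_zero(self, default_model):
        assert align_nostutter("AAAA", "AAA", np.zeros(3), default_model) == 0.0

    @pytest.mark.parametrize("L", [1, 2, 3, 4])
    def test_sum_over_reads_is_total_no_stutter_mass(self, L, default_model):
        """Summing the no-stutter likelihood over every same-length read
        sequence returns 1 - u - d (agreement normalization)."""
        import itertools

        x = ("ACGT" * 2)[:L]
        e = np.full(L, 0.02)
        total = sum(align_nostutter(x, "".join(y), e, default_model)
                    for y in itertools.product("ACGT", repeat=L))
        assert total == pytest.approx(1.0 - 0.02, abs=1e-12)


def brute_del(x, y, e, m, lru):
    dL = len(x) - len(y)
    terms = []
    for k in range(len(x) - dL + 1):
        t = x[:k] + x[k + dL:]
        terms.append(np.prod([1 - ei if a == b else ei / 3
                              for a, b, ei in zip(t, y, e)]))
    steps = max(1, round(dL / lru))
    return m.d * m.rho * (1 - m.rho) ** (steps - 1) * float(np.mean(terms))


def brute_ins(x, y, e, m, lru):
    dL = len(y) - len(x)
    total = 0.0
    for k in range(len(x) + 1):
        terms = []
        if k + dL <= len(x):
            t = x[:k] + x[k: k + dL] + x[k:]
            terms.append(np.prod([1 - ei if a == b else ei / 3
                                  for a, b, ei in zip(t, y, e)]))
        if k - dL >= 0:
            t = x[:k] + x[k - dL: k] + x[k:]
            terms.append(np.prod([1 - ei if a == b else ei / 3
                                  for a, b, ei in zip(t, y, e)]))
        if terms:
            total += float(np.mean(terms))
    steps = max(1, round(dL / lru))
    return m.u * m.rho * (1 - m.rho) ** (steps - 1) * total / (len(x) + 1)


class TestStutterScenarios:
    def test_homopolymer_deletion_value(self, default_model):
        assert align_stutter_del("AAAAA", "AAAA", np.zeros(4),
                                 default_model, 1) == pytest.approx(0.009)

    def test_homopolymer_insertion_value(self, default_model):
        assert align_stutter_ins("AAAA", "AAAAA", np.zeros(5),
                                 default_model, 1) == pytest.approx(0.009)

    def test_homopolymer_ins_del_symmetry_when_u_equals_d(self):
        m = StutterModel(0.03, 0.03, 0.85)
        for L in (4, 6, 9):
            # error-free reads: the two length relations see the same bases
            x, y = "A" * L, "A" * (L - 1)
            dele = align_stutter_del(x, y, np.zeros(L - 1), m, 1)
            ins = align_stutter_ins(y, x, np.zeros(L), m, 1)
            assert dele == pytest.approx(ins, rel=1e-12)

    def test_inapplicable_branches_zero(self, default_model):
        x = "AAAA"
        assert align_stutter_del(x, x, np.zeros(4), default_model, 1) == 0.0
        assert align_stutter_ins(x, x, np.zeros(4), default_model, 1) == 0.0

    def test_matches_brute_force_enumeration(self):
        """Placement/direction-averaged likelihoods equal exhaustive
        enumeration for |X|, |Y| <= 12 to 1e-12."""
        m = StutterModel(0.05, 0.08, 0.8)
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(300):
            Lx = int(rng.integers(2, 13))
            Ly = int(rng.integers(2, 13))
            if Lx == Ly:
                continue
            x = "".join(rng.choice(list("ACGT"), Lx))
            y = "".join(rng.choice(list("ACGT"), Ly))
            e = rng.uniform(0.001, 0.05, Ly)
            lru = int(rng.choice([1, 2, 3]))
            if Lx > Ly:
                got = align_stutter_del(x, y, e, m, lru)
                want = brute_del(x, y, e, m, lru)
            else:
                got = align_stutter_ins(x, y, e, m, lru)
                want = brute_ins(x, y, e, m, lru)
            assert got == pytest.approx(want, abs=1e-12)
            checked += 1
        assert checked > 200

    def test_exactly_one_scenario_applies(self, default_model):
        x, e = "ACGTACGT", np.full(12, 0.01)
        for y in ("ACGTACGT", "ACGTA", "ACGTACGTACGT"):
            vals = [align_nostutter(x, y, e[: len(y)], default_model),
                    align_stutter_del(x, y, e[: len(y)], default_model, 4),
                    align_stutter_ins(x, y, e[: len(y)], default_model, 4)]
            assert sum(v > 0 for v in vals) == 1


class TestHaplotypeAssignment:
    def _pool(self):
        return [Allele("CAG" * 8, "AATTA", "GGCTT", origin="reference"),
                Allele("CAG" * 9, "AATTA", "GGCTT")]

    def test_single_allele_posterior_one(self, default_model):
        pool = self._pool()[:1]
        y = pool[0].padded_seq
        post = assign_read_to_haplotype(y, np.full(len(y), 0.01), pool,
                                        default_model, 3)
        assert post[0] == pytest.approx(1.0)

    def test_matching_allele_dominates(self, default_model):
        pool = self._pool()
        y = pool[0].padded_seq
        post = assign_read_to_haplotype(y, np.full(len(y), 0.01), pool,
                                        default_model, 3)
        assert post[0] > post[1]
        assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_pool_rejected(self, default_model):
        with pytest.raises(ValueError):
            assign_read_to_haplotype("ACGT", np.zeros(4), [],
                                     default_model, 1)


class TestRefineMutation:
    def test_unit_insertion(self):
        germ = Allele("CAG" * 8, "AATTA", "GGCTT")
        mut = Allele("CAG" * 9, "AATTA", "GGCTT")
        desc = refine_mutation(mut, germ)
        assert desc.type == "insertion"
        assert desc.size == 3

    def test_core_substitution_is_mismatch(self):
        germ = Allele("CAG" * 8, "AATTA", "GGCTT")
        mut = Allele("CAG" * 4 + "CGG" + "CAG" * 3, "AATTA", "GGCTT")
        desc = refine_mutation(mut, germ)
        assert desc.type == "mismatch"
        assert desc.size == 0

    def test_deletion_left_aligned_offset(self):
        germ = Allele("A" * 14, "GGCTC", "TCGGC")
        mut = Allele("A" * 7, "GGCTC", "TCGGC")
        desc = refine_mutation(mut, germ)
        assert desc.type == "deletion"
        assert desc.size == 7
        # leftmost equivalent placement: at the start of the homopolymer
        assert desc.position_offset == 0

    def test_identical_alleles_no_mutation(self):
        a = Allele("CAG" * 8, "AATTA", "GGCTT")
        assert refine_mutation(a, a).type == "none"
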