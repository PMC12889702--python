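"""Segmentation HMM: structure, emissions, Viterbi exactness, fallback."""
import numpy as np
import pytest

from mosaicstr.segmentation import (FLANK_R, KNOWN_R, build_locus_hmm,
                                    emission_prob, expected_exit_length,
                                    fallback_segment, segment_read,
                                    segment_reads)
from mosaicstr.types import BASES, STRLocus

from conftest import make_read


def _locus(motif, copies=8, left="TTA", right="GGC"):
    return STRLocus(chrom="1", start=1000, end=1000 + len(motif) * copies,
                    motif=motif, ref_allele_seq=motif * copies,
                    left_flank_3bp=left, right_flank_3bp=right)


class TestStructure:
    def test_str_block_states_cycle_in_motif_order(self, cag_locus):
        hmm = build_locus_hmm(cag_locus)
        str_states = [i for i, k in enumerate(hmm.state_kinds) if k == 2]
        assert [hmm.expected_bases[s] for s in str_states] == ["C", "A", "G"]

    @pytest.mark.parametrize("motif,L", [("A", 5), ("AT", 4), ("CAG", 6),
                                         ("AGAT", 8), ("AGCGT", 10),
                                         ("ACGTAC", 12)])
    def test_exit_length_rule(self, motif, L):
        assert expected_exit_length(motif) == L
        hmm = build_locus_hmm(_locus(motif))
        str_states = np.nonzero(hmm.state_kinds == 2)[0]
        kr0 = np.nonzero(hmm.state_kinds == KNOWN_R)[0][0]
        for s in str_states:
            assert hmm.transition_matrix[s, kr0] == pytest.approx(1.0 / L)

    def test_rows_stochastic(self, cag_locus):
        hmm = build_locus_hmm(cag_locus)
        np.testing.assert_allclose(hmm.transition_matrix.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_invalid_interruption_trans_rejected(self, cag_locus):
        with pytest.raises(ValueError):
            build_locus_hmm(cag_locus, interruption_trans=0.0)
        with pytest.raises(ValueError):
            build_locus_hmm(cag_locus, interruption_trans=1.5)


class TestEmission:
    def test_match_and_mismatch(self):
        assert emission_prob("A", "A", 0.001) == pytest.approx(0.999)
        assert emission_prob("A", "C", 0.003) == pytest.approx(0.001)

    def test_normalized_over_observed_bases(self):
        for e in (0.0, 0.01, 0.3):
            total = sum(emission_prob("A", b, e) for b in BASES)
            assert total == pytest.approx(1.0)

    def test_ambiguous_base_uniform(self):
        assert emission_prob("A", "N", 0.01) == 0.25


class TestViterbiSegmentation:
    def test_perfect_read_boundaries(self, cag_locus):
        hmm = build_locus_hmm(cag_locus)
        seq = "GGTCACGTTA" + "CAG" * 8 + "GGCTTACGAT"
        seg = segment_read(hmm, make_read(seq))
        assert (seg.str_start, seg.str_end) == (10, 34)
        assert seg.method == "hmm"
        assert np.isfinite(seg.viterbi_log_likelihood)

    def test_flank_mutation_keeps_boundaries(self, cag_locus):
        hmm = build_locus_hmm(cag_locus)
        seq = "GGTCTCGTTA" + "CAG" * 8 + "GGCTTACGAT"  # A->T in left flank
        seg = segment_read(hmm, make_read(seq))
        assert (seg.str_start, seg.str_end) == (10, 34)

    def test_pure_flank_read_is_no_repeat(self, cag_locus):
        hmm = build_locus_hmm(cag_locus)
        assert segment_read(hmm, make_read("GGTCTCGATCGCATTGCGAT")) is None

    def test_deterministic(self, cag_locus):
        hmm = build_locus_hmm(cag_locus)
        seq = "GGTCACGTTA" + "CAG" * 8 + "GGCTTACGAT"
        a = segment_read(hmm, make_read(seq))
        b = segment_read(hmm, make_read(seq))
        assert (a.str_start, a.str_end, a.viterbi_log_likelihood) == \
            (b.str_start, b.str_end, b.viterbi_log_likelihood)

    @pytest.mark.parametrize("motif", ["A", "AT", "CAG", "AGAT", "AGCGT",
                                       "ACGTAC"])
    def test_error_free_reads_recover_construction_boundaries(self, motif):
        """On clean reads the HMM boundaries equal the construction
        boundaries for every read across motif lengths 1-6."""
        rng = np.random.default_rng(7)
        copies = 8 if len(motif) <= 3 else 5
        hits = total = 0
        for _ in range(40):
            left = _rand_flank(rng, motif[0], 8)
            right = _rand_flank(rng, motif[-1], 8, last=False)
            locus = STRLocus("1", 1000, 1000 + len(motif) * copies, motif,
                             motif * copies, left[-3:], right[:3])
            hmm = build_locus_hmm(locus)
            seq = left + motif * copies + right
            seg = segment_read(hmm, make_read(seq, e=0.001))
            total += 1
            if seg is not None and seg.str_start == len(left) \
                    and seg.str_end == len(left) + len(motif) * copies:
                hits += 1
        assert hits == total

    def test_batch_matches_single(self, cag_locus):
        hmm = build_locus_hmm(cag_locus)
        seqs = ["GGTCACGTTA" + "CAG" * 8 + "GGCTTACGAT",
                "CGATTA" + "CAG" * 5 + "GGCAT",
                "GGTCTCGATCGCATTGCGAT"]
        reads = [make_read(s, read_id=f"r{i}") for i, s in enumerate(seqs)]
        batch = segment_reads(hmm, reads)
        for read, got in zip(reads, batch):
            single = segment_read(hmm, read)
            if single is None:
                assert got is None
            else:
                assert (got.str_start, got.str_end) == \
                    (single.str_start, single.str_end)
                assert got.viterbi_log_likelihood == pytest.approx(
                    single.viterbi_log_likelihood)


def _rand_flank(rng, avoid, n, last=True):
    """Random flank that does not extend the repeat run at its junction."""
    bases = [b for b in BASES]
    s = "".join(rng.choice(bases, size=n))
    if last and s[-1] == avoid:
        s = s[:-1] + ("C" if avoid != "C" else "G")
    if not last and s[0] == avoid:
        s = ("C" if avoid != "C" else "G") + s[1:]
    return s


def _brute_force_viterbi(hmm, sequence, e):
    """Exhaustive DFS over the sparse transition graph (short reads only)."""
    with np.errstate(divide="ignore"):
        log_T = np.log(hmm.transition_matrix)
        log_pi = np.log(hmm.initial_probs)
    log_E = hmm.log_emissions(sequence, np.full(len(sequence), e))
    succ = [np.nonzero(hmm.transition_matrix[s] > 0)[0]
            for s in range(hmm.n_states)]
    best = [-np.inf, None]

    def dfs(t, s, score, path):
        score = score + log_E[t, s]
        if t == len(sequence) - 1:
            if score > best[0]:
                best[0], best[1] = score, list(path) + [s]
            return
        for s2 in succ[s]:
            dfs(t + 1, s2, score + log_T[s, s2], path + [s])

    for s in np.nonzero(hmm.initial_probs > 0)[0]:
        dfs(0, s, log_pi[s], [])
    return best[0], np.array(best[1])


class TestViterbiExactness:
    @pytest.mark.parametrize("motif", ["A", "AT", "CAG"])
    def test_viterbi_equals_exhaustive_dfs_on_short_reads(self, motif):
        rng = np.random.default_rng(5)
        copies = 3
        locus = _locus(motif, copies=copies)
        hmm = build_locus_hmm(locus)
        for _ in range(5):
            n_left = int(rng.integers(1, 4))
            seq = ("TTA"[-n_left:] + motif * copies)[:8]
            read = make_read(seq, e=0.01)
            seg = segment_read(hmm, read)
            ll_bf, _path = _brute_force_viterbi(hmm, seq, 0.01)
            assert seg is not None
            assert seg.viterbi_log_likelihood == pytest.approx(ll_bf,
                                                               abs=1e-9)

    @pytest.mark.parametrize("motif", ["A", "AT", "CAG", "AGAT", "AGCGT",
                                       "ACGTAC"])
    def test_viterbi_agrees_with_independent_decoder(self, motif):
        """Decoded path probability and boundaries agree with hmmlearn's
        Viterbi on reads up to 25 bp for every motif length."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(13)
        e = 0.01
        copies = max(2, 12 // len(motif))
        locus = _locus(motif, copies=copies)
        hmm = build_locus_hmm(locus)
        ref = hmmlearn.CategoricalHMM(n_components=hmm.n_states,
                                      init_params="", params="")
        ref.startprob_ = hmm.initial_probs
        ref.transmat_ = hmm.transition_matrix
        emis = np.empty((hmm.n_states, 4))
        for s in range(hmm.n_states):
            for b_idx, b in enumerate(BASES):
                emis[s, b_idx] = 0.25 if hmm.expected_bases[s] is None else \
                    (1 - e if hmm.expected_bases[s] == b else e / 3)
        ref.emissionprob_ = emis
        for trial in range(20):
            n_left = int(rng.integers(3, 6))
            n_right = int(rng.integers(3, 6))
            seq = ("GCT" + "TTA")[-n_left:] + motif * copies + \
                ("GGC" + "ACT")[:n_right]
            seq = seq[:25]
            obs = np.array([[BASES.index(b)] for b in seq])
            ll_ref, path_ref = ref.decode(obs, algorithm="viterbi")
            seg = segment_read(hmm, make_read(seq, e=e))
            core_ref = np.array([hmm.is_core_state(s) for s in path_ref])
            assert seg is not None
            assert seg.viterbi_log_likelihood == pytest.approx(ll_ref,
                                                               abs=1e-8)
            idx = np.nonzero(core_ref)[0]
            assert (seg.str_start, seg.str_end) == (idx[0], idx[-1] + 1)


class TestFallback:
    def test_clean_projection(self, cag_locus):
        seq = "GGTCACGTTA" + "CAG" * 8 + "GGCTTACGAT"
        read = make_read(seq, ref_start=990, ref_end=1034,
                         cigartuples=[(0, len(seq))])
        seg = fallback_segment(read, cag_locus)
        assert seg.method == "fallback"
        assert seg.str_seq == "CAG" * 8

    def test_deletion_shortens_core(self, cag_locus):
        seq = "GGTCACGTTA" + "CAG" * 7 + "GGCTTACGAT"
        read = make_read(seq, ref_start=990, ref_end=1034,
                         cigartuples=[(0, 31), (2, 3), (0, 10)])
        seg = fallback_segment(read, cag_locus)
        assert len(seg.str_seq) == 21

    def test_insertion_lengthens_core(self, cag_locus):
        seq = "GGTCACGTTA" + "CAG" * 9 + "GGCTTACGAT"
        read = make_read(seq, ref_start=990, ref_end=1034,
                         cigartuples=[(0, 34), (1, 3), (0, 10)])
        seg = fallback_segment(read, cag_locus)
        assert len(seg.str_seq) == 27

    def test_partial_coverage_returns_none(self, cag_locus):
        seq = "GGTCACGTTA" + "CAG" * 4  # ends inside the STR
        read = make_read(seq, ref_start=990, ref_end=1012,
                         cigartuples=[(0, len(seq))])
        assert fallback_segment(read, cag_locus) is None
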