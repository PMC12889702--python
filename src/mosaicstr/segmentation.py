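"""Probabilistic read segmentation with a three-block hidden Markov model.

Each locus gets a small HMM with an STR block (one state per motif base,
cycling in motif order), an interruption block (an insert state and a
mismatch state per motif position; deletions are skip transitions), and a
flanking block (a generic uniform-emission state plus the locus's known 3 bp
flank states on each side).  Read-to-segment boundaries come from the
Viterbi path; a CIGAR-projection fallback covers reads the HMM cannot
segment (large deletions below the step length, interrupted 4-6 bp motifs).

Emission model: the expected base of a state receives probability ``1 - e``
and each other base ``e / 3``, where ``e`` is the per-base sequencing error
rate; uniform states emit 0.25 for every base, and an observed ``N`` is
scored 0.25 in every state.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .types import BASES, ObservedRead, ReadSegmentation, STRLocus

NEG_INF = -np.inf

# state kind tags
FLANK_L, KNOWN_L, STR, INS, MIS, KNOWN_R, FLANK_R = range(7)


def expected_exit_length(motif: str) -> int:
    """Expected segmentation distance L before leaving the STR block.

    5 bp for homopolymers, twice the motif length otherwise; the initial
    STR-to-flank transition probability is 1/L.
    """
    return 5 if len(motif) == 1 else 2 * len(motif)


def emission_prob(expected_base: str, observed_base: str, e: float) -> float:
    """P(observed | expected) under the per-base error model."""
    if not 0.0 <= e < 1.0:
        raise ValueError(f"error rate {e} outside [0, 1)")
    if observed_base not in BASES:
        return 0.25
    if expected_base is None:
        return 0.25
    return 1.0 - e if observed_base == expected_base else e / 3.0


@dataclass
class SegmentationHMM:
    """Locus-specific segmentation HMM (dense row-stochastic transitions)."""

    motif: str
    state_kinds: np.ndarray          # kind tag per state
    expected_bases: list             # expected base per state (None = uniform)
    transition_matrix: np.ndarray    # (S, S)
    initial_probs: np.ndarray        # (S,)
    L_exit: int

    @property
    def n_states(self) -> int:
        return len(self.state_kinds)

    def is_core_state(self, s: int) -> bool:
        return self.state_kinds[s] in (STR, INS, MIS)

    def log_emissions(self, sequence: str, errors: np.ndarray) -> np.ndarray:
        """Per-position log emission matrix of shape (len(seq), n_states)."""
        L, S = len(sequence), self.n_states
        out = np.empty((L, S))
        for t, (obs, e) in enumerate(zip(sequence, errors)):
            for s in range(S):
                out[t, s] = np.log(emission_prob(self.expected_bases[s], obs, e))
        return out


def build_locus_hmm(locus: STRLocus, interruption_trans: float = 0.01) -> SegmentationHMM:
    """Construct the three-block HMM for one locus.

    The STR block has exactly ``len(motif)`` states cycling in motif order;
    the initial STR-to-flank transition equals ``1 / L_exit``.
    """
    if not 0.0 < interruption_trans < 1.0:
        raise ValueError(f"interruption_trans must lie in (0, 1): {interruption_trans}")
    motif = locus.motif.upper()
    m = len(motif)
    if not 1 <= m <= 6:
        raise ValueError(f"motif length must be in [1, 6]: {motif!r}")
    L_exit = expected_exit_length(motif)
    p_exit = 1.0 / L_exit
    p_int = interruption_trans

    kinds: List[int] = []
    expected: List[Optional[str]] = []

    def add(kind: int, base: Optional[str]) -> int:
        kinds.append(kind)
        expected.append(base)
        return len(kinds) - 1

    def flank_bases(fl3: str) -> list:
        return [b if b in BASES else None
                for b in (fl3.upper() if fl3 else "NNN")]

    fl = add(FLANK_L, None)
    kl = [add(KNOWN_L, b) for b in flank_bases(locus.left_flank_3bp)]
    s_states = [add(STR, motif[i]) for i in range(m)]
    i_states = [add(INS, None) for _ in range(m)]
    x_states = [add(MIS, None) for _ in range(m)]
    kr = [add(KNOWN_R, b) for b in flank_bases(locus.right_flank_3bp)]
    fr = add(FLANK_R, None)

    S = len(kinds)
    T = np.zeros((S, S))
    # left flank: linger, then commit to the 3 bp known flank leading into the STR
    T[fl, fl] = 0.9
    T[fl, kl[0]] = 0.1
    T[kl[0], kl[1]] = 1.0
    T[kl[1], kl[2]] = 1.0
    T[kl[2], s_states[0]] = 1.0
    for i in range(m):
        s = s_states[i]
        nxt = s_states[(i + 1) % m]
        skip = s_states[(i + 2) % m]
        T[s, kr[0]] += p_exit
        T[s, i_states[i]] += p_int          # insertion
        T[s, x_states[i]] += p_int          # mismatch interruption
        if m > 1:
            T[s, skip] += p_int             # single-base deletion (skip)
            T[s, nxt] += 1.0 - p_exit - 3 * p_int
        else:
            T[s, nxt] += 1.0 - p_exit - 2 * p_int
        T[i_states[i], i_states[i]] = 0.3
        T[i_states[i], nxt] = 0.7
        T[x_states[i], s_states[(i + 2) % m] if m > 1 else s_states[0]] = 1.0
    T[kr[0], kr[1]] = 1.0
    T[kr[1], kr[2]] = 1.0
    T[kr[2], fr] = 1.0
    T[fr, fr] = 1.0

    pi = np.zeros(S)
    pi[fl] = 0.70
    for k in kl:
        pi[k] = 0.05
    for s in s_states:
        pi[s] = 0.15 / m
    pi /= pi.sum()

    rowsum = T.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-9):
        raise AssertionError(f"non-stochastic transition rows: {rowsum}")
    return SegmentationHMM(motif=motif, state_kinds=np.array(kinds),
                           expected_bases=expected, transition_matrix=T,
                           initial_probs=pi, L_exit=L_exit)


def _viterbi(log_pi: np.ndarray, log_T: np.ndarray, log_E: np.ndarray):
    """Standard log-space Viterbi.  Returns (path, log_likelihood)."""
    L, S = log_E.shape
    dp = log_pi + log_E[0]
    back = np.zeros((L, S), dtype=np.int32)
    for t in range(1, L):
        cand = dp[:, None] + log_T
        back[t] = np.argmax(cand, axis=0)
        dp = cand[back[t], np.arange(S)] + log_E[t]
    path = np.empty(L, dtype=np.int32)
    path[-1] = int(np.argmax(dp))
    ll = float(dp[path[-1]])
    for t in range(L - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, ll


def viterbi_batch(hmm: SegmentationHMM, sequences: Sequence[str],
                  errors: Sequence[np.ndarray]):
    """Viterbi over a batch of reads, padded to a common length.

    Returns a list of (path, log_likelihood) pairs, one per read.
    """
    with np.errstate(divide="ignore"):
        log_T = np.log(hmm.transition_matrix)
        log_pi = np.log(hmm.initial_probs)
    lens = np.array([len(s) for s in sequences])
    Lmax, S, R = int(lens.max()), hmm.n_states, len(sequences)
    # per-read per-position emissions; padded positions are zeros (ignored)
    log_E = np.zeros((R, Lmax, S))
    base_idx = {b: i for i, b in enumerate(BASES)}
    exp_idx = np.array([base_idx.get(b, -1) if b else -1 for b in hmm.expected_bases])
    uniform = exp_idx < 0
    for r, (seq, err) in enumerate(zip(sequences, errors)):
        obs = np.array([base_idx.get(b, -1) for b in seq])
        e = np.asarray(err, dtype=float)[:, None]
        match = obs[:, None] == exp_idx[None, :]
        em = np.where(match, 1.0 - e, e / 3.0)
        em[:, uniform] = 0.25
        em[obs < 0, :] = 0.25
        log_E[r, : len(seq)] = np.log(em)

    dp = log_pi[None, :] + log_E[:, 0, :]
    back = np.zeros((R, Lmax, S), dtype=np.int32)
    finals = np.empty((R, S))
    done = lens == 1
    finals[done] = dp[done]
    for t in range(1, Lmax):
        cand = dp[:, :, None] + log_T[None, :, :]
        bp = np.argmax(cand, axis=1)
        back[:, t, :] = bp
        dp = np.take_along_axis(cand, bp[:, None, :], axis=1)[:, 0, :] + log_E[:, t, :]
        done = lens == t + 1
        finals[done] = dp[done]
    out = []
    for r in range(R):
        Lr = int(lens[r])
        path = np.empty(Lr, dtype=np.int32)
        path[-1] = int(np.argmax(finals[r]))
        ll = float(finals[r, path[-1]])
        for t in range(Lr - 1, 0, -1):
            path[t - 1] = back[r, t, path[t]]
        out.append((path, ll))
    return out


def _segmentation_from_path(read: ObservedRead, path: np.ndarray, ll: float,
                            hmm: SegmentationHMM) -> Optional[ReadSegmentation]:
    core = np.array([hmm.is_core_state(s) for s in path])
    if not core.any():
        return None
    idx = np.nonzero(core)[0]
    s0, s1 = int(idx[0]), int(idx[-1]) + 1
    return ReadSegmentation(
        read_id=read.read_id, str_start=s0, str_end=s1,
        str_seq=read.sequence[s0:s1],
        left_flank_seq=read.sequence[:s0],
        right_flank_seq=read.sequence[s1:],
        viterbi_log_likelihood=ll, method="hmm")


def segment_read(hmm: SegmentationHMM, read: ObservedRead) -> Optional[ReadSegmentation]:
    """Segment one read by the maximum-likelihood Viterbi path.

    Returns None when the optimal path never enters the STR block
    (the no-repeat outcome); callers may fall back to coordinate projection.
    """
    with np.errstate(divide="ignore"):
        log_T = np.log(hmm.transition_matrix)
        log_pi = np.log(hmm.initial_probs)
    log_E = hmm.log_emissions(read.sequence, read.base_error_rates)
    path, ll = _viterbi(log_pi, log_T, log_E)
    return _segmentation_from_path(read, path, ll, hmm)


def segment_reads(hmm: SegmentationHMM, reads: Sequence[ObservedRead]
                  ) -> List[Optional[ReadSegmentation]]:
    """Batched Viterbi segmentation of many reads at one locus."""
    if not reads:
        return []
    results = viterbi_batch(hmm, [r.sequence for r in reads],
                            [r.base_error_rates for r in reads])
    return [_segmentation_from_path(rd, p, ll, hmm)
            for rd, (p, ll) in zip(reads, results)]


def fallback_segment(read: ObservedRead, locus: STRLocus) -> Optional[ReadSegmentation]:
    """Coordinate-projection backup: project catalog coordinates through
    the read's alignment (CIGAR walk).

    Returns None when the alignment does not cover both locus boundaries
    (partial coverage; the read is excluded from allele generation).
    """
    if read.cigartuples is None or read.ref_start < 0:
        return None

    def project(target: int):
        """Map a reference coordinate to a query offset via the CIGAR walk."""
        ref, qry = read.ref_start, 0
        if target < ref:
            return None
        # CIGAR ops: 0=M,1=I,2=D,3=N,4=S,7==,8=X (pysam encoding)
        for op, length in read.cigartuples:
            if op in (0, 7, 8):      # consumes both
                if ref <= target < ref + length:
                    return qry + (target - ref)
                ref += length
                qry += length
            elif op in (1, 4):       # consumes query only
                qry += length
            elif op in (2, 3):       # consumes reference only
                if ref <= target < ref + length:
                    return qry
                ref += length
        return qry if target == ref else None

    s0, s1 = project(locus.start), project(locus.end)
    if s0 is None or s1 is None or s1 > len(read.sequence):
        return None
    return ReadSegmentation(
        read_id=read.read_id, str_start=s0, str_end=s1,
        str_seq=read.sequence[s0:s1],
        left_flank_seq=read.sequence[:s0],
        right_flank_seq=read.sequence[s1:],
        viterbi_log_likelihood=float("nan"), method="fallback")


def grid_search_interruption(locus: STRLocus, labeled_reads, true_bounds,
                             grid=(0.001, 0.005, 0.01, 0.05, 0.1)) -> float:
    """Pick the interruption transition maximizing exact-boundary accuracy
    on user-provided labeled reads (a small stand-in for a panel-wide search).
    """
    best, best_acc = grid[0], -1.0
    for p in grid:
        hmm = build_locus_hmm(locus, p)
        hits = 0
        for read, (s0, s1) in zip(labeled_reads, true_bounds):
            seg = segment_read(hmm, read)
            if seg is not None and seg.str_start == s0 and seg.str_end == s1:
                hits += 1
        acc = hits / max(len(true_bounds), 1)
        if acc > best_acc:
            best, best_acc = p, acc
    return best
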