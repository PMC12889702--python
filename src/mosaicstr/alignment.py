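"""Sequence-level candidate alleles and STR-specific alignment likelihoods.

Segmented read cores are promoted to candidate alleles (core plus 5 bp of
reference flank on each side).  A read is then scored against each allele
under three mutually exclusive scenarios decided by the length relation:
no stutter (equal lengths), stutter deletion (read shorter), and stutter
insertion (read longer, modeled as a local duplication of adjacent
sequence).  Deletion likelihoods average over every placement; insertion
likelihoods average over placements and duplication directions, with edge
placements restricted to their single feasible direction.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .stutter import StutterModel
from .types import Allele, AlignmentScore, MutationDescription, ReadSegmentation, STRLocus


def agreement_score(x_base: str, y_base: str, e: float) -> float:
    """Per-base agreement: 1 - e on match, e / 3 on mismatch."""
    return 1.0 - e if x_base == y_base else e / 3.0


def _q_profile(x: str, y: str, e: np.ndarray) -> np.ndarray:
    """Vector of agreement scores Q(x_i, y_i); e indexed by read (y) position."""
    xs = np.frombuffer(x.encode(), dtype=np.uint8)
    ys = np.frombuffer(y.encode(), dtype=np.uint8)
    return np.where(xs == ys, 1.0 - e, e / 3.0)


def build_candidate_alleles(segmentations: Sequence[Optional[ReadSegmentation]],
                            locus: STRLocus,
                            left_pad: str, right_pad: str,
                            min_support: int = 2,
                            max_alleles: int = 8) -> List[Allele]:
    """Promote distinct full-span read cores with enough support to alleles.

    The reference allele is always first.  Pads are 5 bp of reference flank.
    """
    ref = Allele(core_str_seq=locus.ref_allele_seq, left_pad_5bp=left_pad,
                 right_pad_5bp=right_pad, origin="reference")
    counts: Dict[str, int] = {}
    for seg in segmentations:
        if seg is None or not seg.str_seq:
            continue
        # full-span requirement: flanking sequence present on both sides
        if not seg.left_flank_seq or not seg.right_flank_seq:
            continue
        counts[seg.str_seq] = counts.get(seg.str_seq, 0) + 1
    ref.support = counts.get(locus.ref_allele_seq, 0)
    pool = [ref]
    promoted = [(c, s) for s, c in counts.items()
                if c >= min_support and s != locus.ref_allele_seq]
    promoted.sort(key=lambda t: (-t[0], t[1]))
    for c, s in promoted[: max_alleles - 1]:
        pool.append(Allele(core_str_seq=s, left_pad_5bp=left_pad,
                           right_pad_5bp=right_pad, support=c))
    return pool


def align_nostutter(x: str, y: str, e: np.ndarray, model: StutterModel) -> float:
    """Equal-length scenario: (1 - u - d) times the product of agreements."""
    if len(x) != len(y):
        return 0.0
    return (1.0 - model.u - model.d) * float(np.prod(_q_profile(x, y, np.asarray(e))))


def _unit_steps(delta_len: int, motif_len: int) -> int:
    return max(1, int(np.rint(delta_len / motif_len)))


def align_stutter_del(x: str, y: str, e: np.ndarray, model: StutterModel,
                      motif_len: int) -> float:
    """Read shorter than allele: average the spliced agreement product over
    every deletion placement, scaled by the geometric deletion mass."""
    dL = len(x) - len(y)
    if dL < 1:
        return 0.0
    e = np.asarray(e)
    steps = _unit_steps(dL, motif_len)
    factor = model.d * model.rho * (1.0 - model.rho) ** (steps - 1)
    L, Ly = len(x), len(y)
    n_place = L - dL + 1
    # A[i] = Q(x_i, y_i) for the unspliced prefix, B[i] = Q(x_{i+dL}, y_i)
    # for the spliced suffix; placement k (0-based deletion start) scores
    # prefix(A[:k]) * suffix(B[k:]).
    a = _q_profile(x[:Ly], y, e)
    b = _q_profile(x[dL:], y, e)
    pref = np.concatenate([[1.0], np.cumprod(a)])          # pref[k] = prod A[:k]
    suff = np.concatenate([np.cumprod(b[::-1])[::-1], [1.0]])
    total = float(np.dot(pref[:n_place], suff[:n_place]))
    return factor * total / n_place


def align_stutter_ins(x: str, y: str, e: np.ndarray, model: StutterModel,
                      motif_len: int) -> float:
    """Read longer than allele: sum over insertion positions, duplicating
    from the right at the left edge, from the left at the right edge, and
    averaging both directions in the interior; scaled by 1/(L+1) and the
    geometric insertion mass."""
    dL = len(y) - len(x)
    if dL < 1:
        return 0.0
    e = np.asarray(e)
    steps = _unit_steps(dL, motif_len)
    L = len(x)
    factor = model.u * model.rho * (1.0 - model.rho) ** (steps - 1) / (L + 1)
    # A[i] = Q(x_i, y_i) (prefix before the insertion), C[i] = Q(x_i, y_{i+dL})
    # (suffix after it).  Insertion after x position k (0-based count):
    #   right-duplication template = x[:k] + x[k:k+dL] + x[k:], whose first
    #   k + dL bases match A and whose tail matches C from index k;
    #   left-duplication template = x[:k] + x[k-dL:k] + x[k:], prefix A up to
    #   k then C from index k - dL.
    a = _q_profile(x, y[:L], e[:L])
    c = _q_profile(x, y[dL:], e[dL:])
    pref = np.concatenate([[1.0], np.cumprod(a)])            # pref[m] = prod A[:m]
    suffc = np.concatenate([np.cumprod(c[::-1])[::-1], [1.0]])  # suffc[m] = prod C[m:]
    total = 0.0
    for k in range(0, L + 1):
        terms = []
        if k + dL <= L:
            terms.append(pref[k + dL] * suffc[k])
        if k - dL >= 0:
            terms.append(pref[k] * suffc[k - dL])
        if terms:
            total += sum(terms) / len(terms)
    return factor * total


def score_read_against_allele(allele: Allele, read_padded: str, e: np.ndarray,
                              model: StutterModel, motif_len: int,
                              allele_id: int = 0) -> AlignmentScore:
    x, y = allele.padded_seq, read_padded
    with np.errstate(divide="ignore"):
        return AlignmentScore(
            allele_id=allele_id,
            log_nostutter=float(np.log(max(align_nostutter(x, y, e, model), 0.0)
                                       or 0.0) if len(x) == len(y) else -np.inf),
            log_stutter_del=float(np.log(align_stutter_del(x, y, e, model, motif_len))
                                  if len(x) > len(y) else -np.inf),
            log_stutter_ins=float(np.log(align_stutter_ins(x, y, e, model, motif_len))
                                  if len(x) < len(y) else -np.inf),
        )


def read_allele_likelihood(allele: Allele, read_padded: str, e: np.ndarray,
                           model: StutterModel, motif_len: int) -> float:
    """Scenario-resolved likelihood P(read | allele); exactly one scenario
    applies for a given length relation."""
    x, y = allele.padded_seq, read_padded
    if len(x) == len(y):
        return align_nostutter(x, y, e, model)
    if len(x) > len(y):
        return align_stutter_del(x, y, e, model, motif_len)
    return align_stutter_ins(x, y, e, model, motif_len)


def assign_read_to_haplotype(read_padded: str, e: np.ndarray,
                             pool: Sequence[Allele], model: StutterModel,
                             motif_len: int) -> Optional[np.ndarray]:
    """Normalized posterior over alleles for one read; None if every
    likelihood is zero (unassignable, excluded downstream)."""
    if not pool:
        raise ValueError("empty allele pool")
    lik = np.array([read_allele_likelihood(a, read_padded, e, model, motif_len)
                    for a in pool])
    tot = lik.sum()
    if tot <= 0.0:
        return None
    return lik / tot


# ---------------------------------------------------------------------------
# mutation refinement


def refine_mutation(mutant: Allele, germline: Allele) -> MutationDescription:
    """Describe the mutant-vs-germline difference (type, size, left-aligned
    offset) from a pairwise comparison including 4 bp flanks."""
    m = mutant.left_pad_5bp[1:] + mutant.core_str_seq + mutant.right_pad_5bp[:4]
    g = germline.left_pad_5bp[1:] + germline.core_str_seq + germline.right_pad_5bp[:4]
    if m == g:
        return MutationDescription(type="none", size=0, position_offset=0,
                                   mutant_allele=mutant.core_str_seq,
                                   germline_allele=germline.core_str_seq)
    size = len(m) - len(g)
    prefix = 0
    for a, b in zip(m, g):
        if a != b:
            break
        prefix += 1
    if size > 0:
        mtype, msize = "insertion", size
    elif size < 0:
        mtype, msize = "deletion", -size
    else:
        mtype, msize = "mismatch", 0
    if mtype == "mismatch":
        offset = prefix - 4  # relative to the STR core start
        micro = False
    else:
        # leftmost equivalent indel placement: a gap at position p is valid
        # iff the first p bases match and the remaining suffix matches, so
        # the smallest valid p is len(shorter) - (common suffix length)
        shorter, longer = (m, g) if size < 0 else (g, m)
        suffix = 0
        for a, b in zip(reversed(m), reversed(g)):
            if a != b or suffix >= len(shorter):
                break
            suffix += 1
        p = max(0, len(shorter) - suffix)
        p = min(p, prefix)
        offset = p - 4
        inserted = longer[p: p + msize]
        ctx = longer[p + msize: p + 2 * msize]
        micro = bool(inserted) and inserted == ctx
    return MutationDescription(type=mtype, size=msize, position_offset=offset,
                               mutant_allele=mutant.core_str_seq,
                               germline_allele=germline.core_str_seq,
                               microhomology=micro)


def refine_mutation_aligned(mutant: Allele, germline: Allele) -> MutationDescription:
    """Variant of :func:`refine_mutation` backed by a global pairwise
    alignment (match +1, mismatch -1, gap open -2, gap extend -0.5),
    used when sequences differ by more than a single contiguous event."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    m = mutant.left_pad_5bp[1:] + mutant.core_str_seq + mutant.right_pad_5bp[:4]
    g = germline.left_pad_5bp[1:] + germline.core_str_seq + germline.right_pad_5bp[:4]
    if m == g:
        return MutationDescription(type="none", size=0, position_offset=0,
                                   mutant_allele=mutant.core_str_seq,
                                   germline_allele=germline.core_str_seq)
    aln = aligner.align(g, m)[0]
    g_blocks, m_blocks = aln.aligned
    size = len(m) - len(g)
    if size != 0:
        return refine_mutation(mutant, germline)
    # equal length with >= 1 substitution
    offset = None
    for (gs, ge), (ms, me) in zip(g_blocks, m_blocks):
        seg_g, seg_m = g[gs:ge], m[ms:me]
        for i, (a, b) in enumerate(zip(seg_g, seg_m)):
            if a != b:
                offset = gs + i - 4
                break
        if offset is not None:
            break
    return MutationDescription(type="mismatch", size=0,
                               position_offset=offset if offset is not None else 0,
                               mutant_allele=mutant.core_str_seq,
                               germline_allele=germline.core_str_seq)
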