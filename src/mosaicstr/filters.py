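"""Phasing-discordance rates, the dual-mode hard-filter cascade, and the
cross-validation binomial tests.

A true mosaic mutation arises on exactly one haplotype, so reads linking
the germline allele j to haplotype h1 and the mutant allele k to h2 should
be internally consistent.  Four discordance rates summarize violations:
d_bulk (mutant-allele reads on the germline haplotype in bulk), d_sc (the
same over all cells), d_amp (germline-allele reads on the mutant haplotype
in the mutant cell — amplification error), and d_k (mutant-allele reads on
the wrong haplotype in the mutant cell).  Phase-informed calls must keep
all four rates below 0.1 with mutant-cell VAF >= 0.1 and >= 2 mutant
reads; non-phaseable calls need VAF > 0.25 and >= 3 mutant reads.
"""
from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

from scipy.stats import binom, binomtest

from .types import CandidateCall, PhasingRates


def _rate(num: int, den: int) -> Optional[float]:
    if num < 0 or den < 0:
        raise ValueError("negative read counts")
    return None if den == 0 else num / den


def compute_phasing_rates(bulk_counts: Tuple[int, int, int, int],
                          sc_counts: Tuple[int, int, int, int],
                          mutant_counts: Tuple[int, int, int, int]) -> PhasingRates:
    """Discordance rates from (n_j_h1, n_k_h1, n_j_h2, n_k_h2) count tables.

    Convention: germline allele j links h1, mutant allele k links h2.
    A zero denominator yields None (undefined); the hard filter treats an
    undefined rate as a failure.
    """
    bj1, bk1, _, _ = bulk_counts
    sj1, sk1, _, _ = sc_counts
    mj1, mk1, mj2, mk2 = mutant_counts
    return PhasingRates(
        d_bulk=_rate(bk1, bj1 + bk1),
        d_sc=_rate(sk1, sj1 + sk1),
        d_amp=_rate(mj2, mj2 + mk2),
        d_k=_rate(mk1, mk1 + mk2),
    )


def apply_hard_filters(call: CandidateCall, mode: str,
                       phasing_rate_max: float = 0.1,
                       phased_vaf_min: float = 0.1, phased_alt_min: int = 2,
                       unphased_vaf_min: float = 0.25,
                       unphased_alt_min: int = 3) -> Tuple[bool, Dict[str, bool]]:
    """Evaluate the mode-specific hard filters; returns (pass, rule trace)."""
    trace: Dict[str, bool] = {}
    if mode == "phase":
        rates = call.phasing_rates
        if rates is None:
            trace["unphasable"] = False
            return False, trace
        for name, value in rates.as_dict().items():
            trace[f"{name}_lt_{phasing_rate_max}"] = (
                value is not None and value < phasing_rate_max)
        trace[f"vaf_ge_{phased_vaf_min}"] = call.vaf >= phased_vaf_min
        trace[f"alt_ge_{phased_alt_min}"] = call.alt_reads >= phased_alt_min
    elif mode == "nophase":
        trace[f"vaf_gt_{unphased_vaf_min}"] = call.vaf > unphased_vaf_min
        trace[f"alt_ge_{unphased_alt_min}"] = call.alt_reads >= unphased_alt_min
    else:
        raise ValueError(f"unknown filter mode: {mode!r}")
    return all(trace.values()), trace


def validate_call_binomial(k: int, n: int,
                           theta0: Sequence[float] = (0.5,)) -> str:
    """One-sided lower-tail binomial validation of a call against an
    orthogonal read set (duplicate library or RNA).

    P = P(X <= k | n, theta0); when several null fractions are supplied
    (e.g. the model-derived expected mutant fraction and 0.5), the larger
    P is retained.  Returns "validated" (P >= 0.05 and k > 0),
    "unvalidated" (P < 0.05 or k == 0) or "undetermined" (no coverage).
    """
    if n == 0:
        return "undetermined"
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    p_val = max(float(binom.cdf(k, n, t)) for t in theta0)
    if p_val >= 0.05 and k > 0:
        return "validated"
    return "unvalidated"


def bulk_germline_gate(bulk_pileups: Sequence[Tuple[int, int]]) -> str:
    """Classify a call against matched bulk samples (blood + normal tissue).

    A locus is germline iff, in every provided bulk, the VAF falls in
    [0.4, 0.6] or a two-tailed binomial test against theta = 0.5 gives
    P > 0.05.  Germline calls are routed to unvalidated; anything failing
    in at least one bulk stays a somatic candidate.
    """
    if not bulk_pileups:
        raise ValueError("need at least one bulk pileup")
    for alt, depth in bulk_pileups:
        if depth == 0:
            return "somatic-candidate"
        vaf = alt / depth
        in_window = 0.4 <= vaf <= 0.6
        p = binomtest(alt, depth, 0.5, alternative="two-sided").pvalue
        if not (in_window or p > 0.05):
            return "somatic-candidate"
    return "germline"


def deduplicate_calls(calls: Sequence[CandidateCall]) -> list:
    """Caller-priority de-duplication: for calls at the same (locus, cell),
    a phase-mode verdict outranks a nophase-mode one.  Idempotent."""
    order = {"phase": 0, "nophase": 1, None: 2}
    best: Dict[tuple, CandidateCall] = {}
    for call in calls:
        key = (call.locus.locus_id, call.cell_id)
        mode = call.filter_trace.get("mode")
        if key not in best or order.get(mode, 2) < order.get(
                best[key].filter_trace.get("mode"), 2):
            best[key] = call
    return list(best.values())
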