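"""snATAC-seq adaptation: barcode-aware deduplication, pseudo-bulk
genotyping, the five-rule filter cascade, and per-cell mutation rates.

snATAC coverage is far too sparse for per-cell genotyping, so all cells of
one individual are pooled into a single pseudo-cell and the mosaic
posterior is computed at the individual level with a relaxed cutoff (0.5).
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotyping import site_mutant_count_posterior
from .stutter import StutterModel, stutter_prob_matrix
from .types import ObservedRead


@dataclass
class AtacFragmentGroup:
    """Reads sharing one (cell barcode, fragment start, fragment end)."""

    barcode: str
    start: int
    end: int
    members: List[ObservedRead] = field(default_factory=list)


def group_fragments(reads: Sequence[ObservedRead]) -> List[AtacFragmentGroup]:
    groups: Dict[tuple, AtacFragmentGroup] = {}
    for r in reads:
        key = (r.cell_id, r.ref_start, r.ref_end)
        if key not in groups:
            groups[key] = AtacFragmentGroup(barcode=r.cell_id,
                                            start=r.ref_start, end=r.ref_end)
        groups[key].members.append(r)
    return list(groups.values())


def dedup_atac(groups: Sequence[AtacFragmentGroup]) -> List[ObservedRead]:
    """Within each group, only identical-sequence reads are duplicates;
    among those, keep the read with the highest mapping quality, then the
    highest mean base quality, then the smallest read id (deterministic).
    Idempotent by construction."""
    kept: List[ObservedRead] = []
    for g in groups:
        by_seq: Dict[str, List[ObservedRead]] = defaultdict(list)
        for r in g.members:
            by_seq[r.sequence].append(r)
        for members in by_seq.values():
            members.sort(key=lambda r: (-r.mapping_quality,
                                        -r.mean_base_quality, r.read_id))
            kept.append(members[0])
    kept.sort(key=lambda r: (r.ref_start, r.read_id))
    return kept


@dataclass
class PseudobulkResult:
    posterior: float
    n_reads: int
    germline_genotype: Tuple[int, int]
    mutant_len: Optional[int]
    alt_reads: int


def pseudobulk_genotype(pooled_lengths: Sequence[int],
                        bulk_lengths: Sequence[int],
                        model: StutterModel,
                        mu: float = 0.001) -> Optional[PseudobulkResult]:
    """Length-based mosaic posterior for one individual's pooled cells.

    The germline genotype is taken from the bulk length profile; the pooled
    cells form a single pseudo-cell whose best mutant genotype is compared
    against the germline in the site-posterior machinery (N = 1).
    Returns None when no reads are available.
    """
    pooled = np.asarray(pooled_lengths, dtype=int)
    bulk = np.asarray(bulk_lengths, dtype=int)
    if pooled.size < 1:
        return None
    lens = np.concatenate([pooled, bulk]) if bulk.size else pooled
    alleles = np.unique(lens)
    # germline: maximum-likelihood diploid genotype under the bulk profile
    best_g, best_ll = None, -np.inf
    src = bulk if bulk.size else pooled
    pm = stutter_prob_matrix(src, alleles, model)
    for i in range(len(alleles)):
        for j in range(i, len(alleles)):
            ll = float(np.sum(np.log(np.maximum(
                0.5 * pm[:, i] + 0.5 * pm[:, j], 1e-300))))
            if ll > best_ll:
                best_g, best_ll = (i, j), ll
    j, k = best_g
    pmc = stutter_prob_matrix(pooled, alleles, model)
    lg = float(np.sum(np.log(np.maximum(0.5 * pmc[:, j] + 0.5 * pmc[:, k],
                                        1e-300))))
    best_alt, best_lm = None, -np.inf
    for a in range(len(alleles)):
        if a in (j, k):
            continue
        for g in ((j, a), (a, k)):
            lm = float(np.sum(np.log(np.maximum(
                0.5 * pmc[:, g[0]] + 0.5 * pmc[:, g[1]], 1e-300))))
            if lm > best_lm:
                best_alt, best_lm = a, lm
    if best_alt is None:
        return PseudobulkResult(posterior=0.0, n_reads=int(pooled.size),
                                germline_genotype=(int(alleles[j]),
                                                   int(alleles[k])),
                                mutant_len=None, alt_reads=0)
    sp = site_mutant_count_posterior([best_lm], [lg], mu, as_log=True)
    alt_reads = int(np.sum(pooled == alleles[best_alt]))
    return PseudobulkResult(posterior=sp.mosaic_posterior,
                            n_reads=int(pooled.size),
                            germline_genotype=(int(alleles[j]),
                                               int(alleles[k])),
                            mutant_len=int(alleles[best_alt]),
                            alt_reads=alt_reads)


def apply_atac_filters(candidates: pd.DataFrame,
                       posterior_min: float = 0.5,
                       min_reads: int = 10,
                       max_recurrence: int = 2) -> pd.DataFrame:
    """Retain candidates passing all five rules: posterior > 0.5, > 10
    genotyping reads, bulk homozygous with exactly one alternative read,
    no off-target artifact reads at the locus, and recurrence in fewer
    than two individuals.

    Expects columns: locus_id, individual, posterior, n_reads,
    bulk_homozygous, bulk_alt_reads, n_offtarget_reads.
    """
    df = candidates.copy()
    rec = df.groupby("locus_id")["individual"].transform("nunique")
    keep = (
        (df["posterior"] > posterior_min)
        & (df["n_reads"] > min_reads)
        & df["bulk_homozygous"].astype(bool)
        & (df["bulk_alt_reads"] == 1)
        & (df["n_offtarget_reads"] == 0)
        & (rec < max_recurrence)
    )
    return df[keep].reset_index(drop=True)


@dataclass
class CellMutationSummary:
    cell_id: str
    n_mutations: int
    callable_bp: int

    @property
    def rate(self) -> float:
        if self.callable_bp <= 0:
            raise ValueError(f"cell {self.cell_id} has no callable length")
        return self.n_mutations / self.callable_bp


def per_cell_mutation_rate(summaries: Sequence[CellMutationSummary]) -> float:
    """Individual mutation rate: the mean of per-cell rates M_i / L_i,
    excluding cells with zero callable length (with a warning)."""
    import logging

    rates = []
    for s in summaries:
        if s.callable_bp <= 0:
            logging.getLogger("mosaicstr").warning(
                "excluding cell %s with zero callable length", s.cell_id)
            continue
        rates.append(s.rate)
    if not rates:
        raise ValueError("no cells with callable length")
    return float(np.mean(rates))


def callable_length(reads: Sequence[ObservedRead], loci,
                    mapq_min: int = 20) -> int:
    """Total bp of STR loci covered by >= 1 spanning high-MAPQ read
    (spanning = covering the full repeat interval plus 1 bp each side)."""
    total = 0
    for locus in loci:
        for r in reads:
            if (r.mapping_quality >= mapq_min
                    and r.ref_start <= locus.start - 1
                    and r.ref_end >= locus.end + 1):
                total += locus.end - locus.start
                break
    return total
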