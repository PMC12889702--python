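"""End-to-end orchestration: segmentation -> stutter training -> bias ->
joint genotyping -> site posteriors -> filters -> calls.

Operates on an in-memory cohort (the simulator's output or one assembled
from files via :mod:`mosaicstr.io`); every stage is the corresponding
library function, so the CLI subcommands and this module share one path.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import alignment as aln
from . import genotyping as gt
from .bias import GPBiasModel
from .config import RunConfig
from .filters import apply_hard_filters, compute_phasing_rates
from .segmentation import build_locus_hmm, fallback_segment, segment_reads
from .simulate import SimulatedCohort
from .stutter import (IndividualLengths, LocusLengthData, StutterModel,
                      fit_stutter_em)
from .types import CandidateCall, ObservedRead, PhasingRates, ReadSegmentation, STRLocus

MAX_STUTTER_TRAINING_LOCI = 150
MAX_GP_POINTS = 200


@dataclass
class LocusReadSet:
    """Segmented reads at one locus for one source (bulk or one cell)."""

    reads: List[ObservedRead]
    segs: List[Optional[ReadSegmentation]]

    def full_span(self, pad: int = 5):
        """(read, seg) pairs usable for allele generation: segmented with
        at least ``pad`` bp of flank on both sides."""
        out = []
        for r, s in zip(self.reads, self.segs):
            if s is not None and len(s.left_flank_seq) >= pad \
                    and len(s.right_flank_seq) >= pad:
                out.append((r, s))
        return out


@dataclass
class PipelineResult:
    calls: List[CandidateCall]
    site_table: pd.DataFrame
    stutter_model: StutterModel
    config: RunConfig


def segment_locus(locus: STRLocus, reads: Sequence[ObservedRead],
                  config: RunConfig) -> LocusReadSet:
    """HMM-segment a batch of reads, falling back to coordinate projection
    for reads the Viterbi path cannot segment."""
    reads = list(reads)
    hmm = build_locus_hmm(locus, config.interruption_trans)
    segs = segment_reads(hmm, reads)
    for i, s in enumerate(segs):
        if s is None:
            segs[i] = fallback_segment(reads[i], locus)
    return LocusReadSet(reads=reads, segs=segs)


def segment_locus_sources(locus: STRLocus,
                          sources: Dict[str, Sequence[ObservedRead]],
                          config: RunConfig) -> Dict[str, LocusReadSet]:
    """Segment every source's reads at one locus in a single Viterbi batch."""
    keys = list(sources)
    all_reads = [r for k in keys for r in sources[k]]
    if not all_reads:
        return {k: LocusReadSet(reads=[], segs=[]) for k in keys}
    hmm = build_locus_hmm(locus, config.interruption_trans)
    segs = segment_reads(hmm, all_reads)
    for i, s in enumerate(segs):
        if s is None:
            segs[i] = fallback_segment(all_reads[i], locus)
    out = {}
    pos = 0
    for k in keys:
        n = len(sources[k])
        out[k] = LocusReadSet(reads=list(sources[k]), segs=segs[pos: pos + n])
        pos += n
    return out


def segment_cohort(cohort: SimulatedCohort, config: RunConfig
                   ) -> Dict[str, Dict[str, LocusReadSet]]:
    """Segment the whole cohort, one Viterbi batch per locus."""
    segmented: Dict[str, Dict[str, LocusReadSet]] = {}
    for locus in cohort.loci:
        sources: Dict[str, list] = {}
        for ind in cohort.individuals:
            sources[f"bulk:{ind.individual_id}"] = \
                ind.bulk_reads.get(locus.locus_id, [])
            for cell_id, by_locus in ind.cells.items():
                sources[f"cell:{cell_id}"] = by_locus.get(locus.locus_id, [])
        segmented[locus.locus_id] = segment_locus_sources(locus, sources,
                                                          config)
    return segmented


def _padded_read(seg: ReadSegmentation, pad: int = 5) -> str:
    return (seg.left_flank_seq[-pad:] + seg.str_seq + seg.right_flank_seq[:pad])


def train_stutter(cohort: SimulatedCohort,
                  segmented: Dict[str, Dict[str, LocusReadSet]],
                  config: RunConfig) -> StutterModel:
    """Fit the protocol-level stutter model on pooled length observations."""
    data: List[LocusLengthData] = []
    for locus in cohort.loci[:MAX_STUTTER_TRAINING_LOCI]:
        lid = locus.locus_id
        per_locus = segmented.get(lid)
        if per_locus is None:
            continue
        inds = []
        for ind in cohort.individuals:
            bulk = np.array([len(s.str_seq) for _, s in
                             per_locus[f"bulk:{ind.individual_id}"].full_span()])
            cells = []
            for cell_id in ind.cells:
                key = f"cell:{cell_id}"
                cells.append(np.array(
                    [len(s.str_seq) for _, s in per_locus[key].full_span()]))
            if bulk.size or any(c.size for c in cells):
                inds.append(IndividualLengths(bulk=bulk, cells=cells))
        if inds:
            data.append(LocusLengthData(locus_id=lid, unit=len(locus.motif),
                                        individuals=inds))
    model, _ = fit_stutter_em(data, config)
    return model


def fit_bias_models(cohort: SimulatedCohort,
                    segmented: Dict[str, Dict[str, LocusReadSet]],
                    config: RunConfig) -> Dict[str, GPBiasModel]:
    """Per-cell local-bias models from the hSNP-link fractions at each locus."""
    out: Dict[str, GPBiasModel] = {}
    cell_ids = [cid for ind in cohort.individuals for cid in ind.cells]
    for cell_id in cell_ids:
        positions, afs = [], []
        for locus in cohort.loci:
            per_locus = segmented.get(locus.locus_id)
            if per_locus is None:
                continue
            rs = per_locus.get(f"cell:{cell_id}")
            if rs is None:
                continue
            n1 = sum(1 for r in rs.reads if r.linked_hsnp_allele == "h1")
            n2 = sum(1 for r in rs.reads if r.linked_hsnp_allele == "h2")
            if n1 + n2 == 0:
                continue
            snp = cohort.hsnp_by_locus[locus.locus_id]
            positions.append(snp.pos)
            afs.append(n1 / (n1 + n2))
        if len(positions) > MAX_GP_POINTS:
            idx = np.linspace(0, len(positions) - 1, MAX_GP_POINTS).astype(int)
            positions = [positions[i] for i in idx]
            afs = [afs[i] for i in idx]
        if positions:
            order = np.argsort(positions)
            out[cell_id] = GPBiasModel.fit(
                cell_id, [positions[i] for i in order],
                [afs[i] for i in order], random_state=config.seed)
    return out


def _read_likelihoods(read_sets: Sequence[Tuple[ObservedRead, ReadSegmentation]],
                      pool, model: StutterModel, motif_len: int):
    """P(read | allele) matrix, grouping identical (padded seq, error) reads."""
    cache: Dict[tuple, np.ndarray] = {}
    rows = []
    links = []
    for read, seg in read_sets:
        padded = _padded_read(seg)
        e_level = float(read.base_error_rates[0])
        key = (padded, e_level)
        if key not in cache:
            e = np.full(len(padded), e_level)
            cache[key] = np.array([
                aln.read_allele_likelihood(a, padded, e, model, motif_len)
                for a in pool])
        rows.append(cache[key])
        links.append({"h1": 0, "h2": 1}.get(read.linked_hsnp_allele, -1))
    if not rows:
        return np.zeros((0, len(pool))), np.zeros(0, dtype=int)
    return np.vstack(rows), np.asarray(links, dtype=int)


def call_locus(cohort: SimulatedCohort, locus: STRLocus,
               per_locus: Dict[str, LocusReadSet], model: StutterModel,
               bias: Dict[str, GPBiasModel], config: RunConfig):
    """Genotype one locus and emit candidate calls plus a site summary."""
    motif_len = len(locus.motif)
    all_full = [pair for rs in per_locus.values() for pair in rs.full_span()]
    pool = aln.build_candidate_alleles(
        [s for _, s in all_full], locus,
        left_pad=cohort.reference[locus.chrom][locus.start - 5: locus.start],
        right_pad=cohort.reference[locus.chrom][locus.end: locus.end + 5],
        min_support=config.min_allele_support,
        max_alleles=config.max_pool_alleles)
    n_cells_total = sum(len(ind.cells) for ind in cohort.individuals)
    mean_depth = sum(len(rs.reads) for key, rs in per_locus.items()
                     if key.startswith("cell:")) / max(n_cells_total, 1)
    summary = {"locus_id": locus.locus_id, "n_alleles": len(pool),
               "n_alt_alleles": len(pool) - 1, "mean_cell_depth": mean_depth,
               "posterior": 0.0, "mutant_allele": None}
    if len(pool) < 2 or mean_depth <= 1.0:
        return [], summary

    individuals_data = []
    cell_index: List[Tuple[int, str]] = []
    for ind in cohort.individuals:
        bulk_pairs = per_locus[f"bulk:{ind.individual_id}"].full_span()
        blik, blinks = _read_likelihoods(bulk_pairs, pool, model, motif_len)
        bulk = gt.CellLocusData(cell_id=f"{ind.individual_id}_bulk",
                                read_lik=blik, hsnp_link=blinks,
                                af_h1=0.5, af_usable=True)
        cells = []
        for cell_id in ind.cells:
            pairs = per_locus[f"cell:{cell_id}"].full_span()
            clik, clinks = _read_likelihoods(pairs, pool, model, motif_len)
            af1, usable = 0.5, False
            bm = bias.get(cell_id)
            if bm is not None:
                pred = bm.predict_local_af(locus.start)
                af1, usable = pred.af_h1, pred.usable
            cells.append(gt.CellLocusData(cell_id=cell_id, read_lik=clik,
                                          hsnp_link=clinks, af_h1=af1,
                                          af_usable=usable))
            cell_index.append((len(individuals_data), cell_id))
        individuals_data.append(gt.IndividualLocusData(
            individual_id=ind.individual_id, bulk=bulk, cells=cells))

    state = gt.run_joint_em(individuals_data, len(pool), config)

    calls: List[CandidateCall] = []
    for i_idx, ind_data in enumerate(individuals_data):
        g_star = state.top_genotype(i_idx)
        j, k = g_star
        p = state.phase_p[i_idx]
        p_germ = np.array([gt.phased_cell_likelihood(c, g_star, p)
                           for c in ind_data.cells])
        best = None
        for a in range(len(pool)):
            if a in g_star:
                continue
            p_mut = np.array([
                max(gt.phased_cell_likelihood(c, (j, a), p),
                    gt.phased_cell_likelihood(c, (a, k), p))
                for c in ind_data.cells])
            mu_val = max(state.mu[i_idx][k, a], state.mu[i_idx][j, a],
                         gt.MU_FLOOR)
            sp = gt.site_mutant_count_posterior(p_mut, p_germ, mu_val,
                                                as_log=True)
            if best is None or sp.mosaic_posterior > best[1].mosaic_posterior:
                best = (a, sp, mu_val, p_mut)
        if best is None:
            continue
        a, sp, mu_val, _ = best
        if sp.mosaic_posterior > summary["posterior"]:
            summary["posterior"] = sp.mosaic_posterior
            summary["mutant_allele"] = pool[a].core_str_seq
        for c_local, cell_post in enumerate(sp.cell_mutant_posteriors):
            if cell_post <= 0.5:
                continue
            cell = ind_data.cells[c_local]
            calls.append(_make_call(cohort, locus, pool, a, g_star, cell,
                                    ind_data, sp.mosaic_posterior, mu_val,
                                    config))
    return calls, summary


def _assign_alleles(cell: gt.CellLocusData) -> np.ndarray:
    """Best-supported allele per read (argmax likelihood); -1 if all zero."""
    if cell.n_reads == 0:
        return np.zeros(0, dtype=int)
    lik = cell.read_lik
    out = np.argmax(lik, axis=1)
    out[np.max(lik, axis=1) <= 0] = -1
    return out


def _phase_counts(cell: gt.CellLocusData, mutant: int, mutant_hap: int):
    """(n_j_h1, n_k_h1, n_j_h2, n_k_h2) with h2 relabeled to the mutant
    haplotype; j = any germline allele, k = the mutant allele."""
    assign = _assign_alleles(cell)
    links = cell.hsnp_link
    # relabel: h2 := mutant haplotype
    is_h2 = links == mutant_hap
    is_h1 = (links >= 0) & ~is_h2
    is_k = assign == mutant
    is_j = (assign >= 0) & ~is_k
    return (int(np.sum(is_j & is_h1)), int(np.sum(is_k & is_h1)),
            int(np.sum(is_j & is_h2)), int(np.sum(is_k & is_h2)))


def _make_call(cohort, locus, pool, mutant, g_star, cell, ind_data,
               posterior, mu_val, config) -> CandidateCall:
    assign = _assign_alleles(cell)
    alt_reads = int(np.sum(assign == mutant))
    total = int(np.sum(assign >= 0))
    vaf = alt_reads / total if total else 0.0
    # mutant haplotype: majority link among mutant-allele reads
    links = cell.hsnp_link[assign == mutant]
    linked = links[links >= 0]
    rates = None
    if linked.size:
        mutant_hap = int(np.sum(linked == 1) >= np.sum(linked == 0))
        sc = np.zeros(4, dtype=int)
        for c in ind_data.cells:
            sc += np.array(_phase_counts(c, mutant, mutant_hap))
        rates = compute_phasing_rates(
            _phase_counts(ind_data.bulk, mutant, mutant_hap),
            tuple(sc), _phase_counts(cell, mutant, mutant_hap))
    germline = aln.refine_mutation(pool[mutant], pool[g_star[1]])
    call = CandidateCall(
        locus=locus, cell_id=cell.cell_id,
        mutant_allele=pool[mutant].core_str_seq,
        germline_genotype=(pool[g_star[0]].core_str_seq,
                           pool[g_star[1]].core_str_seq),
        posterior=posterior, mu=mu_val, vaf=vaf, alt_reads=alt_reads,
        total_reads=total, phasing_rates=rates, mutation=germline)
    mode = "phase" if rates is not None else "nophase"
    gate = gt.genotype_posterior_gate(posterior, config.posterior_cutoff)
    hard_ok, trace = apply_hard_filters(
        call, mode, config.phasing_rate_max, config.phased_vaf_min,
        config.phased_alt_min, config.unphased_vaf_min, config.unphased_alt_min)
    trace["mode"] = mode
    trace["posterior_gate"] = gate
    call.filter_trace = trace
    call.passed = bool(gate and hard_ok)
    return call


def run_pipeline(cohort: SimulatedCohort,
                 config: Optional[RunConfig] = None,
                 stutter_model: Optional[StutterModel] = None) -> PipelineResult:
    """Run the full caller on an in-memory cohort."""
    config = config or RunConfig()
    segmented = segment_cohort(cohort, config)

    if stutter_model is None:
        stutter_model = train_stutter(cohort, segmented, config)
    bias = fit_bias_models(cohort, segmented, config)

    # site calling uses a tighter EM budget; parameters are already pooled
    site_config = config.override(em_max_iter=min(config.em_max_iter, 15),
                                  em_tol=max(config.em_tol, 1e-5))
    calls: List[CandidateCall] = []
    site_rows = []
    for locus in cohort.loci:
        locus_calls, summary = call_locus(cohort, locus,
                                          segmented[locus.locus_id],
                                          stutter_model, bias, site_config)
        calls.extend(locus_calls)
        site_rows.append(summary)
    return PipelineResult(calls=calls, site_table=pd.DataFrame(site_rows),
                          stutter_model=stutter_model, config=config)


def evaluate_calls(result: PipelineResult, truth: pd.DataFrame):
    """Recall and precision of passed calls against the simulator truth."""
    truth_keys = {(r.locus_id, r.cell_id)
                  for r in truth.itertuples() if r.mosaic}
    called = {(c.locus.locus_id, c.cell_id) for c in result.calls if c.passed}
    tp = len(called & truth_keys)
    recall = tp / len(truth_keys) if truth_keys else float("nan")
    precision = tp / len(called) if called else float("nan")
    return {"recall": recall, "precision": precision,
            "n_true": len(truth_keys), "n_called": len(called), "tp": tp}
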