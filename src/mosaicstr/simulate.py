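"""Synthetic single-cell STR cohort generator.

Builds a small synthetic reference carrying a catalog of STR loci, draws
germline diploid genotypes from population allele frequencies, and emits
per-cell and bulk reads with the statistical structure the caller models:
geometric stutter slippage around the template allele, per-base sequencing
errors with quality strings, beta-binomially over-dispersed allele-specific
amplification, allelic dropout, a phased heterozygous SNP near every locus,
and spiked-in mosaic mutations recorded in a truth table.

Read base qualities are drawn per read from a small set of phred levels
(Q25/Q30/Q35), mirroring the coarse quality binning of current instruments.
All randomness flows from a single integer seed; identical seeds give
byte-identical cohorts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import BASES, HetSNP, ObservedRead, STRLocus

QUAL_LEVELS = (25, 30, 35)
QUAL_WEIGHTS = (0.25, 0.5, 0.25)
FLANK_LEN = 40
SPACER_LEN = 50
HSNP_OFFSET = 20          # hSNP sits this many bp left of the STR start
READ_LEN = 100


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort (the default "easy" set:
    30x spanning depth, full-haplotype mosaic VAF, u = d = 0.01)."""

    n_individuals: int = 1
    n_cells: int = 10
    n_loci: int = 500
    motifs: Tuple[str, ...] = ("A", "AT", "CAG", "AGAT")
    motif_weights: Tuple[float, ...] = (0.2, 0.3, 0.3, 0.2)
    ref_copies_range: Tuple[int, int] = (6, 10)
    germline_offsets: Tuple[int, ...] = (0, -1, 1)
    germline_offset_freqs: Tuple[float, ...] = (0.7, 0.15, 0.15)
    stutter_u: float = 0.01
    stutter_d: float = 0.01
    stutter_rho: float = 0.9
    depth_mean: float = 30.0
    bulk_depth: float = 60.0
    alpha: float = 10.0
    beta: float = 10.0
    dropout_rate: float = 0.02
    n_mosaic: int = 50
    mosaic_unit_sizes: Tuple[int, ...] = (1, -1, 2, -2)
    cells_per_mutation: int = 1
    mosaic_hap_fraction: float = 1.0   # fraction of one haplotype's reads mutated
    read_len: int = READ_LEN
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stutter_u", "stutter_d", "dropout_rate",
                     "mosaic_hap_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if not 0.0 < self.stutter_rho <= 1.0:
            raise ValueError("stutter_rho outside (0, 1]")
        if self.n_mosaic > self.n_loci:
            raise ValueError("more mosaic sites than loci")
        if self.cells_per_mutation > self.n_cells:
            raise ValueError("more mutant cells than cells")


@dataclass
class SimulatedIndividual:
    individual_id: str
    germline: Dict[str, Tuple[str, str]]                    # locus -> (core h1, core h2)
    bulk_reads: Dict[str, List[ObservedRead]]
    cells: Dict[str, Dict[str, List[ObservedRead]]]         # cell -> locus -> reads


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    reference: Dict[str, str]
    loci: List[STRLocus]
    hsnps: List[HetSNP]
    hsnp_by_locus: Dict[str, HetSNP]
    individuals: List[SimulatedIndividual]
    truth: pd.DataFrame
    read_tract_spans: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def locus_by_id(self, locus_id: str) -> STRLocus:
        return next(l for l in self.loci if l.locus_id == locus_id)


def sample_allelic_imbalance(alpha: float, beta: float, depth: int,
                             rng: np.random.Generator) -> Tuple[int, int]:
    """Beta-binomial split of ``depth`` reads between the two haplotypes."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return 0, 0
    p = rng.beta(alpha, beta)
    n1 = int(rng.binomial(depth, p))
    return n1, depth - n1


def _sample_stutter_delta(u: float, d: float, rho: float,
                          rng: np.random.Generator) -> int:
    x = rng.random()
    if x < 1.0 - u - d:
        return 0
    sign = 1 if x < 1.0 - d else -1
    return sign * (1 + int(rng.geometric(rho)) - 1)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _apply_errors(seq: str, e: float, rng: np.random.Generator) -> str:
    flips = rng.random(len(seq)) < e
    if not flips.any():
        return seq
    out = list(seq)
    for i in np.nonzero(flips)[0]:
        out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _make_cigar(left: int, ref_tract: int, read_tract: int, right: int):
    """Left-aligned CIGAR for a read spanning the STR (pysam op codes)."""
    ops = []
    common = min(ref_tract, read_tract)
    ops.append((0, left + common))
    if read_tract > ref_tract:
        ops.append((1, read_tract - ref_tract))
    elif ref_tract > read_tract:
        ops.append((2, ref_tract - read_tract))
    if right > 0:
        ops.append((0, right))
    return ops


class CohortSimulator:
    """Deterministic cohort generator; see :class:`SimulationConfig`."""

    def __init__(self, config: Optional[SimulationConfig] = None,
                 seed: Optional[int] = None):
        self.config = config or SimulationConfig()
        if seed is not None:
            self.config.seed = seed
        self.rng = np.random.default_rng(self.config.seed)

    # -- reference ----------------------------------------------------------
    def _build_reference(self):
        cfg, rng = self.config, self.rng
        chrom = "sim1"
        parts: List[str] = []
        pos = 0
        loci: List[STRLocus] = []
        hsnps: List[HetSNP] = []
        hsnp_by_locus: Dict[str, HetSNP] = {}
        for _ in range(cfg.n_loci):
            spacer = _random_seq(SPACER_LEN, rng)
            left = _random_seq(FLANK_LEN, rng)
            motif = str(rng.choice(cfg.motifs, p=cfg.motif_weights))
            copies = int(rng.integers(*cfg.ref_copies_range, endpoint=True))
            tract = motif * copies
            # keep flanks from extending the repeat run
            if left[-1] == motif[0]:
                left = left[:-1] + ("C" if motif[0] != "C" else "G")
            right = _random_seq(FLANK_LEN, rng)
            if right[0] == motif[-1]:
                right = ("C" if motif[-1] != "C" else "G") + right[1:]
            start = pos + SPACER_LEN + FLANK_LEN
            end = start + len(tract)
            locus = STRLocus(chrom=chrom, start=start, end=end, motif=motif,
                             ref_allele_seq=tract,
                             left_flank_3bp=left[-3:], right_flank_3bp=right[:3])
            loci.append(locus)
            # phased hSNP in the left flank
            hpos = start - HSNP_OFFSET
            ref_base = left[FLANK_LEN - HSNP_OFFSET]
            alt_base = BASES[(BASES.index(ref_base) + 2) % 4]
            tag = "h2" if rng.random() < 0.5 else "h1"
            snp = HetSNP(chrom=chrom, pos=hpos, ref_base=ref_base,
                         alt_base=alt_base,
                         bulk_vaf=float(np.round(rng.uniform(0.45, 0.55), 3)),
                         haplotype_tag=tag)
            hsnps.append(snp)
            hsnp_by_locus[locus.locus_id] = snp
            parts.extend([spacer, left, tract, right])
            pos = end + FLANK_LEN
        return {chrom: "".join(parts)}, loci, hsnps, hsnp_by_locus

    # -- reads --------------------------------------------------------------
    def _emit_read(self, locus: STRLocus, snp: HetSNP, haplotype: str,
                   core: str, read_tag: str, clean: bool = False) -> ObservedRead:
        cfg, rng = self.config, self.rng
        delta = 0 if clean else _sample_stutter_delta(
            cfg.stutter_u, cfg.stutter_d, cfg.stutter_rho, rng)
        copies = max(len(core) // len(locus.motif) + delta, 1)
        tract = locus.motif * copies
        offset = int(rng.integers(HSNP_OFFSET + 5, 46))   # bases left of the STR
        right_len = cfg.read_len - offset - len(tract)
        if right_len < 5:
            offset = max(HSNP_OFFSET + 5, cfg.read_len - len(tract) - 10)
            right_len = cfg.read_len - offset - len(tract)
        ref = self.reference[locus.chrom]
        left_seq = ref[locus.start - offset: locus.start]
        right_seq = ref[locus.end: locus.end + right_len]
        right_len = len(right_seq)   # may be shorter near the contig end
        seq = left_seq + tract + right_seq
        # place the hSNP allele of this haplotype
        snp_idx = offset - (locus.start - snp.pos)
        base = snp.base_on(haplotype)
        seq = seq[:snp_idx] + base + seq[snp_idx + 1:]
        q = int(rng.choice(QUAL_LEVELS, p=QUAL_WEIGHTS))
        e = 10.0 ** (-q / 10.0)
        if not clean:
            seq = _apply_errors(seq, e, rng)
        link = None
        obs_base = seq[snp_idx]
        if obs_base == snp.ref_base:
            link = "h1" if snp.haplotype_tag == "h2" else "h2"
        elif obs_base == snp.alt_base:
            link = snp.haplotype_tag
        read = ObservedRead(
            read_id=read_tag, cell_id="", sequence=seq,
            base_error_rates=np.full(len(seq), e),
            mapping_quality=60,
            ref_start=locus.start - offset,
            ref_end=locus.end + right_len,
            cigartuples=_make_cigar(offset, len(locus.ref_allele_seq),
                                    len(tract), right_len),
            linked_hsnp_allele=link, source_haplotype=haplotype)
        self._tract_spans[read_tag] = (offset, offset + len(tract))
        return read

    def _germline_cores(self, locus: STRLocus) -> Tuple[str, str]:
        cfg, rng = self.config, self.rng
        copies = len(locus.ref_allele_seq) // len(locus.motif)
        alleles = []
        for _ in range(2):
            off = int(rng.choice(cfg.germline_offsets,
                                 p=cfg.germline_offset_freqs))
            alleles.append(locus.motif * max(copies + off, 2))
        return alleles[0], alleles[1]

    # -- cohort -------------------------------------------------------------
    def simulate(self) -> SimulatedCohort:
        cfg, rng = self.config, self.rng
        self.reference, loci, hsnps, hsnp_by_locus = self._build_reference()
        self._tract_spans: Dict[str, Tuple[int, int]] = {}

        individuals: List[SimulatedIndividual] = []
        truth_rows: List[dict] = []
        counter = 0

        # choose spiked sites and their carriers up front
        mosaic_loci = rng.choice(cfg.n_loci, size=cfg.n_mosaic, replace=False)
        mosaic_plan: Dict[int, dict] = {}
        for li in mosaic_loci:
            ind = int(rng.integers(cfg.n_individuals))
            cells = rng.choice(cfg.n_cells, size=cfg.cells_per_mutation,
                               replace=False)
            mosaic_plan[int(li)] = {
                "individual": ind,
                "cells": [int(c) for c in cells],
                "units": int(rng.choice(cfg.mosaic_unit_sizes)),
                "haplotype": "h1" if rng.random() < 0.5 else "h2",
            }

        for i_idx in range(cfg.n_individuals):
            ind_id = f"ind{i_idx}"
            germline: Dict[str, Tuple[str, str]] = {}
            bulk_reads: Dict[str, List[ObservedRead]] = {}
            cells: Dict[str, Dict[str, List[ObservedRead]]] = {
                f"{ind_id}_cell{c}": {} for c in range(cfg.n_cells)}
            for l_idx, locus in enumerate(loci):
                snp = hsnp_by_locus[locus.locus_id]
                core1, core2 = self._germline_cores(locus)
                germline[locus.locus_id] = (core1, core2)
                plan = mosaic_plan.get(l_idx)
                spiked = plan if plan and plan["individual"] == i_idx else None
                mutant_core = None
                if spiked:
                    copies = len(core1 if spiked["haplotype"] == "h1"
                                 else core2) // len(locus.motif)
                    germ_copies = {len(core1) // len(locus.motif),
                                   len(core2) // len(locus.motif)}
                    new_copies = max(copies + spiked["units"], 2)
                    step = 1 if spiked["units"] > 0 else -1
                    while new_copies in germ_copies or new_copies < 2:
                        new_copies += step
                        if new_copies < 2:
                            step = 1
                            new_copies = max(germ_copies) + 1
                    mutant_core = locus.motif * new_copies
                # bulk: unbiased mixture of germline haplotypes
                depth_b = int(rng.poisson(cfg.bulk_depth))
                n1 = int(rng.binomial(depth_b, 0.5))
                rlist = []
                for hap, core, nn in (("h1", core1, n1),
                                      ("h2", core2, depth_b - n1)):
                    for _ in range(nn):
                        counter += 1
                        r = self._emit_read(locus, snp, hap, core,
                                            f"r{counter}")
                        r.cell_id = f"{ind_id}_bulk"
                        rlist.append(r)
                bulk_reads[locus.locus_id] = rlist
                # cells
                for c_idx in range(cfg.n_cells):
                    cell_id = f"{ind_id}_cell{c_idx}"
                    depth = int(rng.poisson(cfg.depth_mean))
                    n1, n2 = sample_allelic_imbalance(cfg.alpha, cfg.beta,
                                                      depth, rng)
                    if rng.random() < cfg.dropout_rate:
                        if rng.random() < 0.5:
                            n1 = 0
                        else:
                            n2 = 0
                    creads = []
                    for hap, core, nn in (("h1", core1, n1),
                                          ("h2", core2, n2)):
                        for _ in range(nn):
                            counter += 1
                            r = self._emit_read(locus, snp, hap, core,
                                                f"r{counter}")
                            r.cell_id = cell_id
                            creads.append(r)
                    if spiked and c_idx in spiked["cells"]:
                        n_spiked = self.spike_in_mutation(
                            creads, locus, spiked["haplotype"], mutant_core,
                            cfg.mosaic_hap_fraction)
                        truth_rows.append({
                            "locus_id": locus.locus_id, "individual": ind_id,
                            "cell_id": cell_id,
                            "germline_h1": core1, "germline_h2": core2,
                            "haplotype": spiked["haplotype"],
                            "mutant_core": mutant_core,
                            "mutation_units": spiked["units"],
                            "n_spiked_reads": n_spiked,
                            "mosaic": n_spiked > 0,
                        })
                    cells[cell_id][locus.locus_id] = creads
            individuals.append(SimulatedIndividual(
                individual_id=ind_id, germline=germline,
                bulk_reads=bulk_reads, cells=cells))
        truth = pd.DataFrame(truth_rows, columns=[
            "locus_id", "individual", "cell_id", "germline_h1", "germline_h2",
            "haplotype", "mutant_core", "mutation_units", "n_spiked_reads",
            "mosaic"])
        return SimulatedCohort(config=cfg, reference=self.reference, loci=loci,
                               hsnps=hsnps, hsnp_by_locus=hsnp_by_locus,
                               individuals=individuals, truth=truth,
                               read_tract_spans=dict(self._tract_spans))

    # -- spike-in -----------------------------------------------------------
    def spike_in_mutation(self, reads: List[ObservedRead], locus: STRLocus,
                          haplotype: str, mutant_core: str,
                          fraction: float) -> int:
        """Rewrite the STR tract of a fraction of one haplotype's reads to
        the mutant allele.  Returns the number of rewritten reads (0 when
        the target haplotype dropped out; the spike is then skipped)."""
        targets = [r for r in reads if r.source_haplotype == haplotype]
        if not targets:
            return 0
        n = max(1, math.ceil(fraction * len(targets)))
        for r in targets[:n]:
            span = self._tract_spans.get(r.read_id)
            if span is None:
                continue
            s, t = span
            old_len = t - s
            seq = r.sequence[:s] + mutant_core + r.sequence[t:]
            e = r.base_error_rates
            new_e = np.concatenate([e[:s], np.full(len(mutant_core), e[s] if s < len(e)
                                                   else e[-1]), e[t:]])
            r.sequence = seq
            r.base_error_rates = new_e
            right = len(seq) - s - len(mutant_core)
            r.cigartuples = _make_cigar(s, len(locus.ref_allele_seq),
                                        len(mutant_core), right)
            self._tract_spans[r.read_id] = (s, s + len(mutant_core))
        return n


def simulate_cohort(config: Optional[SimulationConfig] = None,
                    seed: Optional[int] = None) -> SimulatedCohort:
    """Generate a cohort under ``config`` (deterministic under ``seed``)."""
    return CohortSimulator(config, seed).simulate()


# ---------------------------------------------------------------------------
# file emission (text SAM / VCF / BED / FASTA / TSV)


def write_cohort(cohort: SimulatedCohort, out_dir) -> Dict[str, str]:
    """Write the cohort as reference FASTA, catalog BED, phased-hSNP VCF,
    per-cell and bulk SAM files, and the truth TSV.  Returns the paths."""
    import pysam

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}

    fasta = out / "reference.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in cohort.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")
    paths["reference"] = str(fasta)

    bed = out / "catalog.bed"
    with open(bed, "w") as fh:
        for locus in cohort.loci:
            fh.write(f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.motif}\n")
    paths["catalog"] = str(bed)

    vcf = out / "hsnps.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in cohort.reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##INFO=<ID=BVAF,Number=1,Type=Float,'
                 'Description="Matched-bulk VAF">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tbulk\n")
        for snp in cohort.hsnps:
            gt = "0|1" if snp.haplotype_tag == "h2" else "1|0"
            fh.write(f"{snp.chrom}\t{snp.pos + 1}\t.\t{snp.ref_base}\t"
                     f"{snp.alt_base}\t.\tPASS\tBVAF={snp.bulk_vaf}\tGT\t{gt}\n")
    paths["hsnps"] = str(vcf)

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": len(seq)}
               for chrom, seq in cohort.reference.items()],
    })

    def write_sam(path, reads_by_locus):
        reads = [r for rl in reads_by_locus.values() for r in rl]
        reads.sort(key=lambda r: (r.ref_start, r.read_id))
        with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
            for r in reads:
                a = pysam.AlignedSegment(header)
                a.query_name = r.read_id
                a.query_sequence = r.sequence
                a.flag = 0
                a.reference_id = 0
                a.reference_start = r.ref_start
                a.mapping_quality = r.mapping_quality
                a.cigartuples = r.cigartuples
                quals = (-10.0 * np.log10(np.clip(r.base_error_rates,
                                                  1e-10, 1.0))).round()
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(int(q) + 33) for q in quals))
                a.set_tag("CB", r.cell_id)
                sam.write(a)
        return str(path)

    for ind in cohort.individuals:
        paths[f"bulk_{ind.individual_id}"] = write_sam(
            out / f"{ind.individual_id}_bulk.sam", ind.bulk_reads)
        for cell_id, by_locus in ind.cells.items():
            paths[f"cell_{cell_id}"] = write_sam(out / f"{cell_id}.sam", by_locus)

    truth = out / "truth.tsv"
    cohort.truth.to_csv(truth, sep="\t", index=False)
    paths["truth"] = str(truth)
    return paths
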