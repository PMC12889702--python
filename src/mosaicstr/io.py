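"""Readers and writers for the external formats the caller consumes.

BED-like STR catalogs, phased-hSNP VCFs, aligned reads (SAM/BAM), and the
call output (VCF 4.2 plus a TSV mirror).  Coordinates are 0-based
half-open internally; BED is consumed as-is and VCF output is 1-based.
Probabilities are rounded to 4 decimals in TSV and 2 in VCF INFO.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import RunConfig
from .types import CandidateCall, HetSNP, ObservedRead, STRLocus

log = logging.getLogger("mosaicstr")


def load_str_catalog(path, fasta_path=None) -> List[STRLocus]:
    """Load a BED-like STR catalog (chrom, start, end, motif).

    Flank context and the reference allele are populated from the supplied
    reference FASTA.  Malformed rows raise with the line number; rows whose
    motif is outside 1-6 bp are rejected with a logged count.
    """
    ref = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        ref = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    loci: List[STRLocus] = []
    rejected = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: expected chrom/start/end/motif, "
                             f"got {raw!r}")
        chrom, start_s, end_s, motif = parts[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if not 1 <= len(motif) <= 6:
            rejected += 1
            continue
        ref_seq = left = right = ""
        if ref is not None:
            seq = str(ref[chrom][:])
            ref_seq = seq[start:end]
            left = seq[max(start - 3, 0): start].rjust(3, "N")
            right = seq[end: end + 3].ljust(3, "N")
        loci.append(STRLocus(chrom=chrom, start=start, end=end,
                             motif=motif.upper(), ref_allele_seq=ref_seq,
                             left_flank_3bp=left, right_flank_3bp=right))
    if rejected:
        log.warning("rejected %d catalog rows with motif length outside [1, 6]",
                    rejected)
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


def load_phased_hsnps(path) -> List[HetSNP]:
    """Load phased heterozygous SNPs from a VCF.

    Only biallelic SNVs with a phased GT and a matched-bulk VAF in
    [0.4, 0.6] (INFO/BVAF, or alt/total from FORMAT/AD) are retained;
    unphased records are skipped with a warning.
    """
    from cyvcf2 import VCF

    out: List[HetSNP] = []
    skipped_unphased = 0
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        gts = rec.genotypes[0]  # [a0, a1, phased]
        if len(gts) < 3 or not gts[2]:
            skipped_unphased += 1
            continue
        a0, a1 = gts[0], gts[1]
        if {a0, a1} != {0, 1}:
            continue
        vaf = rec.INFO.get("BVAF")
        if vaf is None:
            try:
                ad = rec.format("AD")[0]
                vaf = float(ad[1]) / max(float(ad[0] + ad[1]), 1.0)
            except (TypeError, KeyError):
                continue
        if not 0.4 <= vaf <= 0.6:
            continue
        tag = "h2" if (a0, a1) == (0, 1) else "h1"
        out.append(HetSNP(chrom=rec.CHROM, pos=rec.POS - 1, ref_base=rec.REF,
                          alt_base=rec.ALT[0], bulk_vaf=float(vaf),
                          haplotype_tag=tag))
    if skipped_unphased:
        log.warning("skipped %d unphased hSNP records", skipped_unphased)
    return out


def fetch_locus_reads(alignment_path, locus: STRLocus,
                      config: Optional[RunConfig] = None,
                      hsnps: Optional[Sequence[HetSNP]] = None,
                      cell_tag: str = "CB") -> List[ObservedRead]:
    """Fetch reads overlapping a locus from an indexed (or SAM) alignment
    file, applying the MAPQ / mean-base-quality gates and linking each read
    to the nearest covered hSNP within 500 bp.

    Output is sorted by (read_id, start) and therefore invariant under the
    input read order.
    """
    import pysam

    config = config or RunConfig()
    path = str(alignment_path)
    mode = "r" if path.endswith(".sam") else "rb"
    snp = _nearest_hsnp(locus, hsnps, config.hsnp_max_distance) \
        if hsnps else None
    out: List[ObservedRead] = []
    with pysam.AlignmentFile(path, mode) as fh:
        if path.endswith(".sam"):
            it = (a for a in fh if a.reference_name == locus.chrom
                  and a.reference_start is not None
                  and a.reference_start < locus.end
                  and a.reference_end is not None
                  and a.reference_end > locus.start)
        else:
            it = fh.fetch(locus.chrom, locus.start, locus.end)
        for a in it:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            if a.mapping_quality < config.mapq_min:
                continue
            quals = a.query_qualities
            if quals is None or len(quals) == 0:
                continue
            if float(np.mean(quals)) < config.baseq_min:
                continue
            e = 10.0 ** (-np.asarray(quals, dtype=float) / 10.0)
            read = ObservedRead(
                read_id=a.query_name,
                cell_id=a.get_tag(cell_tag) if a.has_tag(cell_tag) else "",
                sequence=a.query_sequence,
                base_error_rates=e,
                mapping_quality=a.mapping_quality,
                ref_start=a.reference_start,
                ref_end=a.reference_end,
                cigartuples=a.cigartuples)
            if snp is not None:
                read.linked_hsnp_allele = _link_read(a, snp)
            out.append(read)
    out.sort(key=lambda r: (r.read_id, r.ref_start))
    return out


def _nearest_hsnp(locus: STRLocus, hsnps: Sequence[HetSNP],
                  max_distance: int) -> Optional[HetSNP]:
    """Nearest hSNP within the window; ties to the smaller coordinate."""
    best = None
    for snp in hsnps:
        if snp.chrom != locus.chrom:
            continue
        dist = min(abs(snp.pos - locus.start), abs(snp.pos - (locus.end - 1)))
        if dist > max_distance:
            continue
        key = (dist, snp.pos)
        if best is None or key < best[0]:
            best = (key, snp)
    return best[1] if best else None


def _link_read(aln, snp: HetSNP) -> Optional[str]:
    pairs = aln.get_aligned_pairs(matches_only=True)
    for qpos, rpos in pairs:
        if rpos == snp.pos:
            base = aln.query_sequence[qpos]
            if base == snp.alt_base:
                return snp.haplotype_tag
            if base == snp.ref_base:
                return "h1" if snp.haplotype_tag == "h2" else "h2"
            return None
    return None


def load_reads_by_locus(alignment_path, loci: Sequence[STRLocus],
                        config: Optional[RunConfig] = None,
                        hsnps: Optional[Sequence[HetSNP]] = None,
                        cell_tag: str = "CB") -> Dict[str, List[ObservedRead]]:
    """Single pass over an alignment file, bucketing quality-passing reads
    by the catalog locus they overlap (loci assumed non-overlapping)."""
    import pysam

    config = config or RunConfig()
    by_chrom: Dict[str, list] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    starts = {c: np.array([l.start for l in ls])
              for c, ls in by_chrom.items()}
    snp_for = {}
    if hsnps:
        for locus in loci:
            snp_for[locus.locus_id] = _nearest_hsnp(
                locus, hsnps, config.hsnp_max_distance)
    out: Dict[str, List[ObservedRead]] = {l.locus_id: [] for l in loci}
    path = str(alignment_path)
    mode = "r" if path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(path, mode) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            chrom = a.reference_name
            if chrom not in by_chrom:
                continue
            idx = int(np.searchsorted(starts[chrom], a.reference_start,
                                      side="right")) - 1
            candidates = []
            if 0 <= idx < len(by_chrom[chrom]):
                candidates.append(by_chrom[chrom][idx])
            if idx + 1 < len(by_chrom[chrom]):
                candidates.append(by_chrom[chrom][idx + 1])
            locus = next((l for l in candidates
                          if a.reference_start < l.end
                          and (a.reference_end or 0) > l.start), None)
            if locus is None:
                continue
            if a.mapping_quality < config.mapq_min:
                continue
            quals = a.query_qualities
            if quals is None or len(quals) == 0 \
                    or float(np.mean(quals)) < config.baseq_min:
                continue
            read = ObservedRead(
                read_id=a.query_name,
                cell_id=a.get_tag(cell_tag) if a.has_tag(cell_tag) else "",
                sequence=a.query_sequence,
                base_error_rates=10.0 ** (-np.asarray(quals, dtype=float)
                                          / 10.0),
                mapping_quality=a.mapping_quality,
                ref_start=a.reference_start,
                ref_end=a.reference_end,
                cigartuples=a.cigartuples)
            snp = snp_for.get(locus.locus_id)
            if snp is not None:
                read.linked_hsnp_allele = _link_read(a, snp)
            out[locus.locus_id].append(read)
    for reads in out.values():
        reads.sort(key=lambda r: (r.read_id, r.ref_start))
    return out


# ---------------------------------------------------------------------------
# call output

_VCF_INFO = (
    ("POST", "Mosaic genotyping posterior"),
    ("MU", "Mosaic allele fraction"),
    ("VAF", "Mutant-cell variant allele fraction"),
    ("ALTC", "Mutant read count in the mutant cell"),
    ("DBULK", "Bulk phasing discordance rate"),
    ("DSC", "Single-cell phasing discordance rate"),
    ("DAMP", "Amplification-error rate"),
    ("DK", "Mutant-cell discordance rate"),
    ("CLASS", "Predicted class"),
)

TSV_COLUMNS = ("chrom", "pos", "end", "motif", "cell_id", "mutant_allele",
               "posterior", "mu", "vaf", "alt_reads", "total_reads",
               "d_bulk", "d_sc", "d_amp", "d_k", "predicted_class", "passed")


def _fmt(value, decimals: int) -> str:
    if value is None:
        return "."
    return f"{round(float(value), decimals):.{decimals}f}"


def write_calls(calls: Sequence[CandidateCall], path, format: str = "vcf",
                contigs: Optional[Dict[str, int]] = None) -> None:
    """Write finalized calls as VCF 4.2 or a one-row-per-(locus, cell) TSV."""
    path = Path(path)
    if format == "tsv":
        import pandas as pd

        rows = []
        for c in calls:
            rates = c.phasing_rates.as_dict() if c.phasing_rates else {}
            rows.append({
                "chrom": c.locus.chrom, "pos": c.locus.start + 1,
                "end": c.locus.end, "motif": c.locus.motif,
                "cell_id": c.cell_id, "mutant_allele": c.mutant_allele,
                "posterior": round(c.posterior, 4), "mu": round(c.mu, 4),
                "vaf": round(c.vaf, 4), "alt_reads": c.alt_reads,
                "total_reads": c.total_reads,
                "d_bulk": None if rates.get("d_bulk") is None
                else round(rates["d_bulk"], 4),
                "d_sc": None if rates.get("d_sc") is None
                else round(rates["d_sc"], 4),
                "d_amp": None if rates.get("d_amp") is None
                else round(rates["d_amp"], 4),
                "d_k": None if rates.get("d_k") is None
                else round(rates["d_k"], 4),
                "predicted_class": c.predicted_class or ".",
                "passed": c.passed,
            })
        pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t",
                                                       index=False)
        return
    if format != "vcf":
        raise ValueError(f"unknown output format: {format!r}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mosaicstr\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for key, desc in _VCF_INFO:
            typ = "String" if key == "CLASS" else (
                "Integer" if key == "ALTC" else "Float")
            fh.write(f'##INFO=<ID={key},Number=1,Type={typ},'
                     f'Description="{desc}">\n')
        fh.write('##INFO=<ID=CELL,Number=1,Type=String,'
                 'Description="Mutant cell">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            rates = c.phasing_rates.as_dict() if c.phasing_rates else {}
            info = [
                f"POST={_fmt(c.posterior, 2)}", f"MU={_fmt(c.mu, 2)}",
                f"VAF={_fmt(c.vaf, 2)}", f"ALTC={c.alt_reads}",
                f"DBULK={_fmt(rates.get('d_bulk'), 2)}",
                f"DSC={_fmt(rates.get('d_sc'), 2)}",
                f"DAMP={_fmt(rates.get('d_amp'), 2)}",
                f"DK={_fmt(rates.get('d_k'), 2)}",
                f"CLASS={c.predicted_class or '.'}",
                f"CELL={c.cell_id}",
            ]
            ref = c.locus.ref_allele_seq or "N"
            alt = c.mutant_allele or "N"
            filt = "PASS" if c.passed else "fail"
            fh.write(f"{c.locus.chrom}\t{c.locus.start + 1}\t.\t{ref}\t{alt}"
                     f"\t.\t{filt}\t{';'.join(info)}\n")


def read_calls_tsv(path):
    """Re-parse a TSV written by :func:`write_calls` (round-trip checks)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t")


def read_calls_vcf(path) -> List[dict]:
    """Re-parse a VCF written by :func:`write_calls` into plain dicts."""
    out = []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#"):
            continue
        chrom, pos, _id, ref, alt, _q, filt, info = raw.split("\t")
        fields = dict(kv.split("=", 1) for kv in info.split(";"))
        rec = {"chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
               "filter": filt}
        for k, v in fields.items():
            if k in ("CLASS", "CELL"):
                rec[k] = v
            elif v == ".":
                rec[k] = None
            elif k == "ALTC":
                rec[k] = int(v)
            else:
                rec[k] = float(v)
        out.append(rec)
    return out
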