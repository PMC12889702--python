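"""Core domain types shared across the caller.

Coordinates are 0-based half-open internally; VCF output is 1-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

BASES = "ACGT"


@dataclass(frozen=True)
class STRLocus:
    """A catalogued short tandem repeat.

    ``ref_allele_seq`` is the reference sequence of ``[start, end)``;
    ``left_flank_3bp``/``right_flank_3bp`` are the 3 bp of reference context
    used as known-flank states by the segmentation HMM.
    """

    chrom: str
    start: int
    end: int
    motif: str
    ref_allele_seq: str = ""
    left_flank_3bp: str = ""
    right_flank_3bp: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"locus end must exceed start: {self}")
        if not 1 <= len(self.motif) <= 6:
            raise ValueError(f"motif length must be in [1, 6]: {self.motif!r}")
        if self.ref_allele_seq and len(self.ref_allele_seq) != self.end - self.start:
            raise ValueError("ref_allele_seq length inconsistent with coordinates")
        for fl in (self.left_flank_3bp, self.right_flank_3bp):
            if fl and len(fl) != 3:
                raise ValueError("flank context must be exactly 3 bp")

    @property
    def ref_repeat_len(self) -> int:
        return self.end - self.start

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.motif}"


@dataclass(frozen=True)
class HetSNP:
    """A phased germline heterozygous SNP used for haplotype assignment.

    ``haplotype_tag`` names the haplotype carrying the alternative base
    ("h1" or "h2"); loading enforces a matched-bulk VAF in [0.4, 0.6].
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    bulk_vaf: float
    haplotype_tag: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt bases must differ")
        if not 0.4 <= self.bulk_vaf <= 0.6:
            raise ValueError(f"hSNP bulk VAF {self.bulk_vaf} outside [0.4, 0.6]")
        if self.haplotype_tag not in ("h1", "h2"):
            raise ValueError("haplotype_tag must be 'h1' or 'h2'")

    def base_on(self, haplotype: str) -> str:
        return self.alt_base if haplotype == self.haplotype_tag else self.ref_base


@dataclass
class ObservedRead:
    """One aligned read overlapping a locus.

    ``base_error_rates`` holds per-base error probabilities derived from
    phred qualities.  ``linked_hsnp_allele`` is "h1"/"h2" when the read also
    covers a nearby phased hSNP and carries one of its alleles.
    """

    read_id: str
    cell_id: str
    sequence: str
    base_error_rates: np.ndarray
    mapping_quality: int
    ref_start: int = -1
    ref_end: int = -1
    cigartuples: Optional[Sequence[tuple]] = None
    linked_hsnp_allele: Optional[str] = None
    source_haplotype: Optional[str] = None  # simulator truth, never used by the caller

    def __post_init__(self) -> None:
        self.base_error_rates = np.asarray(self.base_error_rates, dtype=float)
        if len(self.sequence) != len(self.base_error_rates):
            raise ValueError("sequence and base qualities differ in length")
        if self.mapping_quality < 0:
            raise ValueError("mapping quality must be >= 0")

    @property
    def mean_base_quality(self) -> float:
        e = np.clip(self.base_error_rates, 1e-10, 1.0)
        return float(np.mean(-10.0 * np.log10(e)))


@dataclass
class ReadSegmentation:
    """A read decomposed into left flank / STR core / right flank."""

    read_id: str
    str_start: int
    str_end: int
    str_seq: str
    left_flank_seq: str
    right_flank_seq: str
    viterbi_log_likelihood: float
    method: str  # "hmm" | "fallback"

    def __post_init__(self) -> None:
        if not 0 <= self.str_start <= self.str_end:
            raise ValueError("invalid STR boundaries")


@dataclass
class Allele:
    """A candidate STR allele: core sequence plus 5 bp flanking pads."""

    core_str_seq: str
    left_pad_5bp: str
    right_pad_5bp: str
    support: int = 0
    origin: str = "read-derived"  # "reference" | "read-derived"

    def __post_init__(self) -> None:
        if len(self.left_pad_5bp) != 5 or len(self.right_pad_5bp) != 5:
            raise ValueError("pads must be exactly 5 bp")

    @property
    def padded_seq(self) -> str:
        return self.left_pad_5bp + self.core_str_seq + self.right_pad_5bp

    @property
    def total_len(self) -> int:
        return len(self.padded_seq)


@dataclass
class AlignmentScore:
    allele_id: int
    log_nostutter: float
    log_stutter_del: float
    log_stutter_ins: float

    @property
    def total_log_likelihood(self) -> float:
        return max(self.log_nostutter, self.log_stutter_del, self.log_stutter_ins)

    @property
    def best_scenario(self) -> str:
        vals = {
            "nostutter": self.log_nostutter,
            "stutter_del": self.log_stutter_del,
            "stutter_ins": self.log_stutter_ins,
        }
        return max(vals, key=lambda k: vals[k])


@dataclass
class MutationDescription:
    type: str  # insertion | deletion | mismatch | none
    size: int
    position_offset: int
    mutant_allele: str = ""
    germline_allele: str = ""
    microhomology: bool = False


@dataclass
class PhasingRates:
    """Haplotype-discordance rates; None means an undefined (0-denominator) rate."""

    d_bulk: Optional[float]
    d_sc: Optional[float]
    d_amp: Optional[float]
    d_k: Optional[float]

    def as_dict(self) -> dict:
        return {"d_bulk": self.d_bulk, "d_sc": self.d_sc,
                "d_amp": self.d_amp, "d_k": self.d_k}


@dataclass
class CandidateCall:
    """A putative mosaic STR mutation in one cell at one locus."""

    locus: STRLocus
    cell_id: str
    mutant_allele: str
    germline_genotype: tuple
    posterior: float
    mu: float
    vaf: float
    alt_reads: int
    total_reads: int
    phasing_rates: Optional[PhasingRates] = None
    mutation: Optional[MutationDescription] = None
    predicted_class: Optional[str] = None
    class_probabilities: Optional[np.ndarray] = None
    filter_trace: dict = field(default_factory=dict)
    passed: bool = False
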