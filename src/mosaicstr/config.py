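"""Run configuration: quality gates, model initializations, filter thresholds.

Every threshold can be overridden from a sectioned key=value config file or a
CLI flag; defaults follow the caller's published operating point.
"""
from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass
class RunConfig:
    # read quality gates
    mapq_min: int = 20
    baseq_min: float = 20.0
    # stutter model initialization (u0, d0, rho0)
    stutter_u_init: float = 0.01
    stutter_d_init: float = 0.01
    stutter_rho_init: float = 0.9
    # mosaic fraction prior
    mu_msi_init: float = 0.001
    # EM control
    em_tol: float = 1e-6
    em_max_iter: int = 200
    # joint genotyping
    max_pool_alleles: int = 8
    min_allele_support: int = 2
    hsnp_max_distance: int = 500
    # segmentation
    interruption_trans: float = 0.01
    # posterior and hard-filter thresholds
    posterior_cutoff: float = 0.9
    phasing_rate_max: float = 0.1
    phased_vaf_min: float = 0.1
    phased_alt_min: int = 2
    unphased_vaf_min: float = 0.25
    unphased_alt_min: int = 3
    # ATAC mode
    atac_posterior_cutoff: float = 0.5
    atac_min_reads: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stutter_u_init", "stutter_d_init", "stutter_rho_init",
                     "mu_msi_init", "posterior_cutoff", "phasing_rate_max",
                     "phased_vaf_min", "unphased_vaf_min",
                     "atac_posterior_cutoff", "interruption_trans"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("mapq_min", "em_max_iter", "phased_alt_min",
                     "unphased_alt_min", "max_pool_alleles",
                     "min_allele_support", "atac_min_reads"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name}={v} must be a non-negative integer")

    def override(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a sectioned key = value config file (sections ignored)."""
        values: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line or line.startswith("["):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value, got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = casts.get(types[key], float)(val)
        return cls(**values)

    def to_file(self, path) -> None:
        lines = ["[mosaicstr]"]
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")
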