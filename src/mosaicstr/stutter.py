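"""Geometric stutter-error model and the length-based cohort EM.

In-vitro polymerase slippage shifts a read's repeat length away from its
template allele by whole repeat units.  The shift distribution is
geometric: a read matches its allele with probability ``1 - u - d``,
gains ``n`` units with probability ``u * rho * (1 - rho)**(n-1)`` and
loses ``n`` units with probability ``d * rho * (1 - rho)**(n-1)``.

``fit_stutter_em`` estimates (u, d, rho) together with length-based
population allele frequencies by expectation-maximization across a
multi-individual cohort, treating individual germline genotypes, rare
single-haplotype mosaic branches, and per-read allele assignments as
latent variables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .config import RunConfig


def _lse(a: np.ndarray) -> float:
    """logsumexp for small 1-D arrays (faster than the scipy generic)."""
    m = np.max(a)
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.sum(np.exp(a - m))))

U_FLOOR = 1e-4
D_FLOOR = 1e-4
RHO_MAX = 1.0 - 1e-6
RHO_MIN = 1e-3


@dataclass
class StutterModel:
    """Geometric slippage parameters for one sequencing protocol (or site)."""

    u: float
    d: float
    rho: float
    unit: int = 1  # repeat-unit step size in bp

    def __post_init__(self) -> None:
        if self.u < 0 or self.d < 0 or self.u + self.d >= 1:
            raise ValueError(f"require u, d >= 0 and u + d < 1: u={self.u} d={self.d}")
        if not 0 < self.rho <= 1:
            raise ValueError(f"rho must lie in (0, 1]: {self.rho}")


def units_delta(read_len: int, allele_len: int, unit: int) -> int:
    """Length difference in repeat units, rounded to the nearest whole unit."""
    return int(np.rint((read_len - allele_len) / unit))


def stutter_read_prob(read_len: int, allele_len: int, model: StutterModel) -> float:
    """P(read length | allele length) under the geometric stutter model.

    Deletions larger than the allele itself get probability 0: a read
    cannot delete more repeat units than the template carries.
    """
    if read_len < 0 or allele_len <= 0:
        raise ValueError("lengths must be positive")
    delta = units_delta(read_len, allele_len, model.unit)
    if delta == 0:
        return 1.0 - model.u - model.d
    if delta > 0:
        return model.u * model.rho * (1.0 - model.rho) ** (delta - 1)
    n = -delta
    if n > allele_len // model.unit:
        return 0.0
    return model.d * model.rho * (1.0 - model.rho) ** (n - 1)


def stutter_prob_matrix(read_lens: np.ndarray, allele_lens: np.ndarray,
                        model: StutterModel) -> np.ndarray:
    """Vectorized stutter pmf: shape (n_reads, n_alleles)."""
    r = np.asarray(read_lens)[:, None]
    a = np.asarray(allele_lens)[None, :]
    delta = np.rint((r - a) / model.unit).astype(int)
    absd = np.abs(delta)
    geo = model.rho * (1.0 - model.rho) ** np.maximum(absd - 1, 0)
    out = np.where(delta == 0, 1.0 - model.u - model.d,
                   np.where(delta > 0, model.u * geo, model.d * geo))
    out = np.where((delta < 0) & (absd > a // model.unit), 0.0, out)
    return out


def diploid_likelihood(read_lens: Sequence[int], genotype: tuple,
                       model: StutterModel) -> float:
    """Product over reads of the half-half mixture over the two alleles."""
    j, k = genotype
    lens = np.asarray(read_lens, dtype=int)
    if lens.size == 0:
        return 1.0
    pm = stutter_prob_matrix(lens, np.array([j, k]), model)
    return float(np.prod(0.5 * pm[:, 0] + 0.5 * pm[:, 1]))


# ---------------------------------------------------------------------------
# cohort EM over length observations


@dataclass
class IndividualLengths:
    """One individual's length observations at one locus (in base pairs)."""

    bulk: np.ndarray
    cells: List[np.ndarray]


@dataclass
class LocusLengthData:
    """Length observations at one locus across the cohort."""

    locus_id: str
    unit: int
    individuals: List[IndividualLengths]


@dataclass
class LengthEMState:
    """EM state: per-locus allele pools and frequencies, germline posteriors,
    the mosaic-fraction prior, and the log-likelihood trace."""

    pools: Dict[str, np.ndarray] = field(default_factory=dict)
    freqs: Dict[str, np.ndarray] = field(default_factory=dict)
    germline_posteriors: Dict[str, list] = field(default_factory=dict)
    mu_msi: float = 0.001
    iteration: int = 0
    loglik_trace: List[float] = field(default_factory=list)


def _locus_pool(data: LocusLengthData, min_support: int = 2) -> np.ndarray:
    """Candidate allele lengths (units): lengths seen >= min_support times
    cohort-wide, always including each individual's modal length."""
    counts: Dict[int, int] = {}
    modal = set()
    for ind in data.individuals:
        lens = np.concatenate([ind.bulk] + list(ind.cells)) if ind.cells else ind.bulk
        lens_u = np.rint(lens / data.unit).astype(int)
        for v in lens_u:
            counts[int(v)] = counts.get(int(v), 0) + 1
        if lens_u.size:
            vals, cnt = np.unique(lens_u, return_counts=True)
            modal.add(int(vals[np.argmax(cnt)]))
    pool = {v for v, c in counts.items() if c >= min_support} | modal
    return np.array(sorted(v for v in pool if v > 0), dtype=int)


def _genotype_pairs(n: int) -> List[tuple]:
    return [(j, k) for j in range(n) for k in range(j, n)]


class _LocusEngine:
    """Per-locus sufficient statistics for one EM iteration."""

    def __init__(self, data: LocusLengthData, pool_units: np.ndarray):
        self.data = data
        self.pool = pool_units
        self.unit = data.unit
        self.pairs = _genotype_pairs(len(pool_units))
        # cache read lengths in units
        self.bulk_u = [np.rint(ind.bulk / self.unit).astype(int)
                       for ind in data.individuals]
        self.cells_u = [[np.rint(c / self.unit).astype(int) for c in ind.cells]
                        for ind in data.individuals]

    def read_probs(self, lens_u: np.ndarray, model: StutterModel) -> np.ndarray:
        unit_model = StutterModel(model.u, model.d, model.rho, unit=1)
        return stutter_prob_matrix(lens_u, self.pool, unit_model)

    def e_step(self, model: StutterModel, f: np.ndarray, mu: float):
        """Exact posteriors over (germline genotype, per-cell branch) plus
        per-read source-allele responsibilities and the locus log-likelihood.
        """
        n_pool = len(self.pool)
        pairs = self.pairs
        stats = {"ins": 0.0, "del": 0.0, "events": 0.0, "steps": 0.0, "n_reads": 0}
        f_post = np.zeros(n_pool)
        loglik = 0.0
        posteriors = []
        for i_idx in range(len(self.data.individuals)):
            bulk_p = self.read_probs(self.bulk_u[i_idx], model)  # (nb, n_pool)
            cell_p = [self.read_probs(c, model) for c in self.cells_u[i_idx]]
            # per-pair log evidence
            log_joint = np.empty(len(pairs))
            # branch bookkeeping per pair per cell for responsibilities
            branch_info = []
            for p_idx, (j, k) in enumerate(pairs):
                prior = f[j] ** 2 if j == k else 2.0 * f[j] * f[k]
                lb = float(np.sum(np.log(0.5 * bulk_p[:, j] + 0.5 * bulk_p[:, k]))) \
                    if bulk_p.size else 0.0
                cell_terms = []
                lcells = 0.0
                for cp in cell_p:
                    branches, weights = _cell_branches(j, k, n_pool, mu)
                    like = np.empty(len(branches))
                    for b_idx, (x, y) in enumerate(branches):
                        if cp.size:
                            like[b_idx] = float(np.sum(
                                np.log(np.maximum(0.5 * cp[:, x] + 0.5 * cp[:, y],
                                                  1e-300))))
                        else:
                            like[b_idx] = 0.0
                    with np.errstate(divide="ignore"):
                        lw = np.log(weights) + like
                    lc = _lse(lw)
                    lcells += lc
                    cell_terms.append((branches, np.exp(lw - lc)))
                log_joint[p_idx] = np.log(max(prior, 1e-300)) + lb + lcells
                branch_info.append(cell_terms)
            tot = _lse(log_joint)
            loglik += tot
            post = np.exp(log_joint - tot)
            posteriors.append(post)
            # accumulate f posterior mass (Hardy-Weinberg bookkeeping)
            for p_idx, (j, k) in enumerate(pairs):
                if j == k:
                    f_post[j] += post[p_idx]
                else:
                    f_post[j] += 0.5 * post[p_idx]
                    f_post[k] += 0.5 * post[p_idx]
            # read-assignment responsibilities -> stutter sufficient stats
            self._accumulate_reads(stats, post, branch_info, bulk_p, cell_p, i_idx)
        return loglik, f_post, stats, posteriors

    def _accumulate_reads(self, stats, post, branch_info, bulk_p, cell_p, i_idx):
        pool = self.pool
        for p_idx, (j, k) in enumerate(self.pairs):
            w_pair = post[p_idx]
            if w_pair < 1e-12:
                continue
            if bulk_p.size:
                self._read_stats(stats, w_pair, bulk_p, (j, k),
                                 self.bulk_u[i_idx], pool)
            for c_idx, cp in enumerate(cell_p):
                branches, bw = branch_info[p_idx][c_idx]
                for (x, y), w_b in zip(branches, bw):
                    if w_pair * w_b < 1e-12 or not cp.size:
                        continue
                    self._read_stats(stats, w_pair * w_b, cp, (x, y),
                                     self.cells_u[i_idx][c_idx], pool)
        stats["n_reads"] += len(self.bulk_u[i_idx]) + sum(
            len(c) for c in self.cells_u[i_idx])

    @staticmethod
    def _read_stats(stats, weight, probs, genotype, lens_u, pool):
        x, y = genotype
        px, py = probs[:, x], probs[:, y]
        denom = np.maximum(0.5 * px + 0.5 * py, 1e-300)
        for a, pa in ((x, px), (y, py)):
            w_a = weight * 0.5 * pa / denom
            delta = lens_u - pool[a]
            ins, dele = delta > 0, delta < 0
            stats["ins"] += float(np.sum(w_a[ins]))
            stats["del"] += float(np.sum(w_a[dele]))
            stats["events"] += float(np.sum(w_a[delta != 0]))
            stats["steps"] += float(np.sum(w_a * np.abs(delta)))


def _cell_branches(j: int, k: int, n_pool: int, mu: float):
    """Cell-genotype branches given germline (j, k): no mutation, or a
    single-haplotype switch to any other pool allele.  Branch weights are
    normalized so that each haplotype mutates with total probability mu/2."""
    branches = [(j, k)]
    weights = [1.0 - mu]
    others_k = [a for a in range(n_pool) if a != k]
    others_j = [a for a in range(n_pool) if a != j]
    if others_k:
        w = 0.5 * mu / len(others_k)
        for a in others_k:
            branches.append((j, a))
            weights.append(w)
    if others_j:
        w = 0.5 * mu / len(others_j)
        for a in others_j:
            branches.append((a, k))
            weights.append(w)
    weights = np.asarray(weights)
    return branches, weights / weights.sum()


def fit_stutter_em(cohort: Sequence[LocusLengthData],
                   config: Optional[RunConfig] = None,
                   min_support: int = 2):
    """Fit (u, d, rho) and per-locus length allele frequencies by EM.

    Returns ``(StutterModel, LengthEMState)``.  The observed-data
    log-likelihood is non-decreasing across iterations (up to numerical
    tolerance); a non-finite likelihood aborts with the iteration index.
    """
    config = config or RunConfig()
    if not cohort:
        raise ValueError("empty cohort")
    model = StutterModel(config.stutter_u_init, config.stutter_d_init,
                         config.stutter_rho_init, unit=1)
    state = LengthEMState(mu_msi=config.mu_msi_init)
    engines = []
    for data in cohort:
        pool = _locus_pool(data, min_support)
        if pool.size == 0:
            continue
        engines.append(_LocusEngine(data, pool))
        state.pools[data.locus_id] = pool * data.unit
        state.freqs[data.locus_id] = np.full(len(pool), 1.0 / len(pool))

    prev_ll = -np.inf
    for it in range(config.em_max_iter):
        total_ll = 0.0
        agg = {"ins": 0.0, "del": 0.0, "events": 0.0, "steps": 0.0, "n_reads": 0}
        for eng in engines:
            f = state.freqs[eng.data.locus_id]
            ll, f_post, stats, posteriors = eng.e_step(model, f, state.mu_msi)
            total_ll += ll
            n_ind = len(eng.data.individuals)
            state.freqs[eng.data.locus_id] = f_post / max(n_ind, 1)
            state.germline_posteriors[eng.data.locus_id] = posteriors
            for key in agg:
                agg[key] += stats[key]
        if not np.isfinite(total_ll):
            raise FloatingPointError(f"non-finite EM log-likelihood at iteration {it}")
        state.loglik_trace.append(total_ll)
        state.iteration = it + 1
        n = max(agg["n_reads"], 1)
        u = max(agg["ins"] / n, U_FLOOR)
        d = max(agg["del"] / n, D_FLOOR)
        if u + d >= 1.0:
            scale = 0.99 / (u + d)
            u, d = u * scale, d * scale
        rho = agg["events"] / agg["steps"] if agg["steps"] > 0 else model.rho
        rho = float(np.clip(rho, RHO_MIN, RHO_MAX))
        model = StutterModel(u=u, d=d, rho=rho, unit=model.unit)
        if prev_ll > -np.inf and abs(total_ll - prev_ll) < config.em_tol * (
                abs(prev_ll) + 1e-12):
            break
        prev_ll = total_ll
    return model, state


def observed_loglik(cohort: Sequence[LocusLengthData], model: StutterModel,
                    state: LengthEMState) -> float:
    """Observed-data log-likelihood at the given parameters (diagnostic)."""
    total = 0.0
    for data in cohort:
        pool_bp = state.pools.get(data.locus_id)
        if pool_bp is None:
            continue
        eng = _LocusEngine(data, np.rint(pool_bp / data.unit).astype(int))
        ll, _, _, _ = eng.e_step(model, state.freqs[data.locus_id], state.mu_msi)
        total += ll
    return total
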