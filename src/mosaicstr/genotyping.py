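"""Hierarchical Bayesian joint genotyping across population, bulk and cells.

The latent structure at one locus: population allele frequencies f (shared
across individuals), an individual germline genotype pair drawn from f
under Hardy-Weinberg (f_j^2 homozygous, 2 f_j f_k heterozygous), per-cell
genotypes that equal the germline pair except for rare single-haplotype
mosaic switches with fraction mu, a phasing orientation linking STR alleles
to hSNP haplotypes, and per-read allele assignments.  The EM alternates
germline-genotype posteriors with updates of f, the phasing probability and
the mosaic fractions.  All likelihood accumulation is in log space.

The site-level question "does any cell carry a mutant allele?" is answered
by a dynamic program over the mutant-cell count L with a binomial(mu)
prior; because the prior puts mass P(L=l)/C(N,l) on each configuration,
it is equivalent to independent Bernoulli(mu) indicators per cell, and the
DP posterior matches exhaustive enumeration exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

from .config import RunConfig


def _lse(a: np.ndarray) -> float:
    """logsumexp for small 1-D arrays (faster than the scipy generic)."""
    m = np.max(a)
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.sum(np.exp(a - m))))

MU_FLOOR = 1e-6
LOG_TINY = -700.0


def prescan_candidates(locus_summaries: Sequence[dict]) -> List[dict]:
    """Keep loci with at least one non-reference allele and mean cell depth > 1.

    Each summary needs keys ``n_alt_alleles`` and ``mean_cell_depth``.
    """
    return [s for s in locus_summaries
            if s["n_alt_alleles"] >= 1 and s["mean_cell_depth"] > 1.0]


def bulk_mosaic_likelihood(r: int, depth: int) -> float:
    """Mosaic genotype likelihood of bulk data under a uniform VAF prior.

    C(depth, r) * B(r + 1, depth - r + 1) — which integrates the binomial
    over theta in [0, 1] and collapses to 1 / (depth + 1) for every r.
    """
    if not 0 <= r <= depth:
        raise ValueError(f"require 0 <= r <= depth, got r={r} depth={depth}")
    log_c = gammaln(depth + 1) - gammaln(r + 1) - gammaln(depth - r + 1)
    return float(np.exp(log_c + betaln(r + 1, depth - r + 1)))


@dataclass
class CellLocusData:
    """Per-cell read evidence at one locus.

    ``read_lik[m, a]`` is P(read m | allele a) from the alignment or length
    engine; ``hsnp_link[m]`` is 0 (h1), 1 (h2) or -1 (read does not cover
    the hSNP).  ``af_h1`` is the predicted local allele fraction of
    haplotype 1 for this cell (0.5 when no usable prediction exists).
    """

    cell_id: str
    read_lik: np.ndarray
    hsnp_link: np.ndarray
    af_h1: float = 0.5
    af_usable: bool = False

    def __post_init__(self) -> None:
        self.read_lik = np.atleast_2d(np.asarray(self.read_lik, dtype=float))
        self.hsnp_link = np.asarray(self.hsnp_link, dtype=int)

    @property
    def n_reads(self) -> int:
        return 0 if self.read_lik.size == 0 else self.read_lik.shape[0]


@dataclass
class IndividualLocusData:
    individual_id: str
    bulk: CellLocusData
    cells: List[CellLocusData]


@dataclass
class CohortGenotypeState:
    """EM state for one locus across the cohort."""

    n_alleles: int
    f: np.ndarray
    germline_posteriors: List[np.ndarray] = field(default_factory=list)
    pairs: List[tuple] = field(default_factory=list)
    phase_p: List[float] = field(default_factory=list)       # per individual
    mu: List[np.ndarray] = field(default_factory=list)       # per individual (k -> a)
    branch_posteriors: List[list] = field(default_factory=list)
    loglik_trace: List[float] = field(default_factory=list)
    iteration: int = 0

    def top_genotype(self, i: int) -> tuple:
        return self.pairs[int(np.argmax(self.germline_posteriors[i]))]


def phased_cell_likelihood(cell: CellLocusData, genotype: Tuple[int, int],
                           phase_p: float) -> float:
    """Log-likelihood of one cell's reads given a genotype.

    Reads covering the hSNP contribute a mixture over (allele, haplotype)
    weighted by the predicted haplotype allele fraction and the phasing
    probability; reads covering only the STR fall back to the plain
    half-half allele mixture.
    """
    if cell.n_reads == 0:
        return 0.0
    x, y = genotype
    lx, ly = cell.read_lik[:, x], cell.read_lik[:, y]
    af1 = cell.af_h1 if cell.af_usable else 0.5
    af2 = 1.0 - af1
    p = phase_p
    term = 0.5 * lx + 0.5 * ly
    h1 = cell.hsnp_link == 0
    h2 = cell.hsnp_link == 1
    if h1.any():
        term = term.copy()
        term[h1] = af1 * (p * lx[h1] + (1.0 - p) * ly[h1])
    if h2.any():
        if not h1.any():
            term = term.copy()
        term[h2] = af2 * ((1.0 - p) * lx[h2] + p * ly[h2])
    return float(np.sum(np.log(np.maximum(term, 1e-300))))


def _genotype_pairs(n: int) -> List[tuple]:
    return [(j, k) for j in range(n) for k in range(j, n)]


def _branches(x: int, y: int, n: int, mu: np.ndarray):
    """Cell-genotype branches for germline (x, y) with per-target mosaic
    fractions mu[k, a]; weights renormalized (double mutations excluded)."""
    mx = float(np.sum(mu[x])) if n > 1 else 0.0
    my = float(np.sum(mu[y])) if n > 1 else 0.0
    branches = [(x, y)]
    weights = [(1.0 - mx) * (1.0 - my)]
    for a in range(n):
        if a != y and mu[y, a] > 0:
            branches.append((x, a))
            weights.append(mu[y, a] * (1.0 - mx))
        if a != x and mu[x, a] > 0:
            branches.append((a, y))
            weights.append(mu[x, a] * (1.0 - my))
    w = np.asarray(weights)
    return branches, w / w.sum()


def run_joint_em(individuals: Sequence[IndividualLocusData], n_alleles: int,
                 config: Optional[RunConfig] = None) -> CohortGenotypeState:
    """EM over germline genotypes, phasing, mosaic fractions and f at one locus."""
    config = config or RunConfig()
    n = n_alleles
    if n < 1:
        raise ValueError("need at least one allele")
    pairs = _genotype_pairs(n)
    state = CohortGenotypeState(
        n_alleles=n, f=np.full(n, 1.0 / n), pairs=pairs,
        phase_p=[0.5] * len(individuals),
        mu=[np.full((n, n), config.mu_msi_init / max(n - 1, 1)) * (1 - np.eye(n))
            if n > 1 else np.zeros((1, 1)) for _ in individuals])

    prev_ll = -np.inf
    for it in range(config.em_max_iter):
        total_ll = 0.0
        f_post = np.zeros(n)
        state.germline_posteriors = []
        state.branch_posteriors = []
        new_phase, new_mu = [], []
        for i_idx, ind in enumerate(individuals):
            p = state.phase_p[i_idx]
            mu = state.mu[i_idx]
            # cache per-cell log-likelihoods: genotype orderings collapse
            cell_cache: List[Dict[tuple, float]] = [dict() for _ in ind.cells]
            bulk_cache: Dict[tuple, float] = {}

            def cell_ll(cell_idx: int, g: tuple) -> float:
                cache = cell_cache[cell_idx]
                if g not in cache:
                    cache[g] = phased_cell_likelihood(
                        individuals[i_idx].cells[cell_idx], g, p)
                return cache[g]

            def bulk_ll(g: tuple) -> float:
                if g not in bulk_cache:
                    bulk_cache[g] = phased_cell_likelihood(
                        individuals[i_idx].bulk, g, p)
                return bulk_cache[g]

            log_joint = np.empty(len(pairs))
            pair_branches = []
            for p_idx, (j, k) in enumerate(pairs):
                prior = state.f[j] ** 2 if j == k else 2.0 * state.f[j] * state.f[k]
                lb = bulk_ll((j, k))
                cell_terms = []
                lcells = 0.0
                branches, bw = _branches(j, k, n, mu)
                log_bw = np.log(np.maximum(bw, 1e-300))
                for c_idx in range(len(ind.cells)):
                    lw = log_bw + np.array([cell_ll(c_idx, g) for g in branches])
                    lc = _lse(lw)
                    lcells += lc
                    cell_terms.append((branches, np.exp(lw - lc)))
                log_joint[p_idx] = np.log(max(prior, 1e-300)) + lb + lcells
                pair_branches.append(cell_terms)
            tot = _lse(log_joint)
            if not np.isfinite(tot):
                raise FloatingPointError(
                    f"non-finite joint-EM likelihood for individual "
                    f"{ind.individual_id} at iteration {it}")
            total_ll += tot
            post = np.exp(log_joint - tot)
            state.germline_posteriors.append(post)
            state.branch_posteriors.append(pair_branches)
            for p_idx, (j, k) in enumerate(pairs):
                if j == k:
                    f_post[j] += post[p_idx]
                else:
                    f_post[j] += 0.5 * post[p_idx]
                    f_post[k] += 0.5 * post[p_idx]
            new_phase.append(_update_phase(ind, pairs, post, p))
            new_mu.append(_update_mu(pairs, post, pair_branches, n,
                                     len(ind.cells)))
        state.f = f_post / max(len(individuals), 1)
        state.phase_p = new_phase
        state.mu = new_mu
        state.loglik_trace.append(total_ll)
        state.iteration = it + 1
        if prev_ll > -np.inf and abs(total_ll - prev_ll) < config.em_tol * (
                abs(prev_ll) + 1e-12):
            break
        prev_ll = total_ll
    return state


def _update_phase(ind: IndividualLocusData, pairs, post, p: float) -> float:
    """M-step for the phasing probability: posterior-weighted fraction of
    dual-covering reads consistent with the current orientation.  Only
    heterozygous genotype pairs and hSNP-linked reads inform the update."""
    num = den = 0.0
    for p_idx, (x, y) in enumerate(pairs):
        if x == y or post[p_idx] < 1e-9:
            continue
        w = post[p_idx]
        for cell in [ind.bulk] + list(ind.cells):
            if cell.n_reads == 0:
                continue
            lx, ly = cell.read_lik[:, x], cell.read_lik[:, y]
            h1 = cell.hsnp_link == 0
            h2 = cell.hsnp_link == 1
            if h1.any():
                r1 = p * lx[h1] / np.maximum(p * lx[h1] + (1 - p) * ly[h1], 1e-300)
                num += w * float(np.sum(r1))
                den += w * float(np.sum(h1))
            if h2.any():
                r1 = p * ly[h2] / np.maximum((1 - p) * lx[h2] + p * ly[h2], 1e-300)
                num += w * float(np.sum(r1))
                den += w * float(np.sum(h2))
    return num / den if den > 0 else 0.5


def _update_mu(pairs, post, pair_branches, n: int, n_cells: int) -> np.ndarray:
    """M-step for mosaic fractions: expected fraction of cells carrying each
    single-haplotype switch, weighted by germline-genotype posteriors."""
    num = np.zeros((n, n))
    den = np.zeros(n)
    for p_idx, (x, y) in enumerate(pairs):
        w = post[p_idx]
        if w < 1e-12 or n_cells == 0:
            continue
        den[x] += w * n_cells
        if y != x:
            den[y] += w * n_cells
        for branches, bw in pair_branches[p_idx]:
            for (bx, by), wb in zip(branches, bw):
                if (bx, by) == (x, y):
                    continue
                if bx == x and by != y:       # slot-2 switch y -> by
                    num[y, by] += w * wb
                elif by == y and bx != x:     # slot-1 switch x -> bx
                    num[x, bx] += w * wb
    mu = np.zeros((n, n))
    mask = den > 0
    mu[mask] = num[mask] / den[mask, None]
    np.fill_diagonal(mu, 0.0)
    return np.clip(mu, 0.0, 0.5)


# ---------------------------------------------------------------------------
# site posterior over the mutant-cell count


@dataclass
class SitePosterior:
    count_posterior: np.ndarray    # P(L = l | data), l = 0..N
    mosaic_posterior: float        # 1 - P(L = 0 | data)
    cell_mutant_posteriors: np.ndarray

    @property
    def top_mutant_cells(self) -> np.ndarray:
        return np.argsort(-self.cell_mutant_posteriors)


def site_mutant_count_posterior(p_mut: Sequence[float], p_germ: Sequence[float],
                                mu: float, as_log: bool = False) -> SitePosterior:
    """DP posterior over the number of mutant cells L.

    ``p_mut[c]`` / ``p_germ[c]`` are each cell's data likelihoods under its
    best mutant and germline genotype; ``mu`` is the locus's mosaic
    fraction (floored at 1e-6 so L = 0 is never absorbing).  Cell-level
    mutant posteriors follow from the equivalent independent-Bernoulli
    form of the prior.
    """
    pm = np.asarray(p_mut, dtype=float)
    pg = np.asarray(p_germ, dtype=float)
    N = pm.size
    if N == 0:
        raise ValueError("need at least one cell")
    if not as_log:
        pm = np.log(np.maximum(pm, 1e-300))
        pg = np.log(np.maximum(pg, 1e-300))
    mu = float(np.clip(mu, MU_FLOOR, 1.0 - MU_FLOOR))
    # DP over log M[l] = log sum over assignments with l mutants of the
    # product of per-cell likelihoods
    M = np.full(N + 1, -np.inf)
    M[0] = 0.0
    for c in range(N):
        new = np.full(N + 1, -np.inf)
        for l in range(c + 2):
            stay = M[l] + pg[c] if l <= c else -np.inf
            move = M[l - 1] + pm[c] if l >= 1 else -np.inf
            new[l] = np.logaddexp(stay, move)
        M = new
    ls = np.arange(N + 1)
    log_post = ls * np.log(mu) + (N - ls) * np.log(1.0 - mu) + M
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)
    lodds = np.log(mu) + pm - np.log(1.0 - mu) - pg
    cell_post = 1.0 / (1.0 + np.exp(-lodds))
    return SitePosterior(count_posterior=post,
                         mosaic_posterior=float(1.0 - post[0]),
                         cell_mutant_posteriors=cell_post)


def genotype_posterior_gate(posterior: float, cutoff: float = 0.9) -> bool:
    """Pass iff the mosaic genotyping posterior reaches the cutoff."""
    return posterior >= cutoff
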