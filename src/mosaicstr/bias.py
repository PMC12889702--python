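"""Whole-genome-amplification allelic bias: global and local models.

Globally, alternative-allele counts of germline heterozygous SNPs at a
fixed median depth are over-dispersed relative to a binomial; they are
modeled with a beta-binomial whose shape parameters come from the
method-of-moments estimator on the first two raw moments.

Locally, amplification bias is correlated along each amplified fragment.
Per cell and chromosome, the phased-hSNP allele-fraction series is
partitioned into independent segments by a two-state Gaussian HMM on the
logit scale, and a zero-mean Gaussian process with an RBF kernel is fitted
within each segment to predict haplotype allele fractions at candidate STR
loci.  Segments whose fit is too noisy (AF-scale MSE > 0.5) are unusable
and downstream consumers substitute an uninformative 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import expit, logit
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

AF_EPS = 1e-7
MSE_MAX = 0.5
GAP_BREAK_BP = 1_000_000
SWITCH_PROB = 0.01


@dataclass
class BetaBinomialParams:
    """Beta-binomial shape parameters fitted at reference median depth dp.

    ``binomial_limit`` marks under-dispersed data where the moment
    denominator is non-positive and no finite (alpha, beta) exists.
    """

    alpha: Optional[float]
    beta: Optional[float]
    dp: int
    binomial_limit: bool = False


def estimate_global_bias(alt_counts: Sequence[int], dp: int,
                         min_sites: int = 100) -> BetaBinomialParams:
    """Method-of-moments beta-binomial fit from hSNP alternative counts.

    m1 and m2 are the first and second raw moments of the counts; the
    estimator requires all sites to share the same (median) depth dp.
    """
    counts = np.asarray(alt_counts, dtype=float)
    if counts.size < min_sites:
        raise ValueError(f"need >= {min_sites} hSNP sites, got {counts.size}")
    m1 = float(np.mean(counts))
    m2 = float(np.mean(counts ** 2))
    if m1 <= 0:
        return BetaBinomialParams(None, None, dp, binomial_limit=True)
    denom = dp * (m2 / m1 - m1 - 1.0) + m1
    if denom <= 0:
        return BetaBinomialParams(None, None, dp, binomial_limit=True)
    alpha = (dp * m1 - m2) / denom
    beta = (dp - m1) * (dp - m2 / m1) / denom
    if alpha <= 0 or beta <= 0:
        return BetaBinomialParams(None, None, dp, binomial_limit=True)
    return BetaBinomialParams(alpha, beta, dp)


def betabinom_moments(alpha: float, beta: float, dp: int):
    """Analytic first and second raw moments of BetaBinomial(dp, alpha, beta)."""
    s = alpha + beta
    m1 = dp * alpha / s
    var = dp * alpha * beta * (s + dp) / (s ** 2 * (s + 1.0))
    return m1, var + m1 ** 2


# ---------------------------------------------------------------------------
# fragment partition


def _two_state_viterbi(y: np.ndarray, switch: float = SWITCH_PROB) -> np.ndarray:
    """Two-state (concordant / shifted) Gaussian HMM Viterbi on a series.

    State means sit at the 25th and 75th percentile of the series with a
    shared standard deviation; deterministic by construction.
    """
    mu = np.percentile(y, [25.0, 75.0])
    sd = max(float(np.std(y)), 0.05)
    log_emis = -0.5 * ((y[:, None] - mu[None, :]) / sd) ** 2
    log_T = np.log(np.array([[1 - switch, switch], [switch, 1 - switch]]))
    dp = np.log(0.5) + log_emis[0]
    back = np.zeros((len(y), 2), dtype=int)
    for t in range(1, len(y)):
        cand = dp[:, None] + log_T
        back[t] = np.argmax(cand, axis=0)
        dp = cand[back[t], [0, 1]] + log_emis[t]
    path = np.empty(len(y), dtype=int)
    path[-1] = int(np.argmax(dp))
    for t in range(len(y) - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def partition_fragments(positions: Sequence[int], afs: Sequence[float],
                        switch_prob: float = SWITCH_PROB,
                        gap_break: int = GAP_BREAK_BP) -> List[slice]:
    """Split one cell-chromosome hSNP series into amplification segments.

    Breakpoints fall where the two-state HMM switches state or where the
    inter-hSNP gap exceeds ``gap_break``.  Segments are contiguous,
    disjoint and cover every hSNP.
    """
    pos = np.asarray(positions)
    af = np.asarray(afs, dtype=float)
    if pos.size != af.size:
        raise ValueError("positions and AFs differ in length")
    if pos.size == 0:
        return []
    if pos.size == 1:
        return [slice(0, 1)]
    if np.any(np.diff(pos) < 0):
        raise ValueError("hSNPs must be sorted by position")
    y = logit(np.clip(af, AF_EPS, 1.0 - AF_EPS))
    states = _two_state_viterbi(y, switch_prob)
    breaks = [0]
    for i in range(1, pos.size):
        if states[i] != states[i - 1] or pos[i] - pos[i - 1] > gap_break:
            breaks.append(i)
    breaks.append(pos.size)
    return [slice(breaks[i], breaks[i + 1]) for i in range(len(breaks) - 1)]


# ---------------------------------------------------------------------------
# piecewise GP regression


@dataclass
class GPSegment:
    """One fitted segment: GP over logit-AF of haplotype h1 versus position."""

    start: int
    end: int
    mse: float
    gp: Optional[GaussianProcessRegressor]
    mean_logit: float
    n_points: int

    @property
    def usable(self) -> bool:
        return self.mse <= MSE_MAX

    def predict_logit(self, position: float) -> float:
        if self.gp is None:
            return self.mean_logit
        return float(self.gp.predict(np.array([[position - self.start]]))[0])


@dataclass
class LocalAFPrediction:
    position: int
    af_h1: float
    af_h2: float
    usable: bool


def fit_segment_gp(positions: Sequence[int], afs: Sequence[float],
                   random_state: int = 0) -> GPSegment:
    """Zero-mean GP with RBF kernel plus a homoscedastic nugget on logit-AF.

    AFs are clamped into (1e-7, 1 - 1e-7) before the logit; the recorded
    MSE is on the AF scale (training predictions versus inputs).
    """
    pos = np.asarray(positions, dtype=float)
    af = np.clip(np.asarray(afs, dtype=float), AF_EPS, 1.0 - AF_EPS)
    y = logit(af)
    start, end = int(pos[0]), int(pos[-1])
    mean_logit = float(np.mean(y))
    if pos.size < 3:
        mse = float(np.mean((expit(np.full_like(af, mean_logit)) - af) ** 2))
        seg = GPSegment(start, end, mse, None, mean_logit, int(pos.size))
        return seg
    x = (pos - start)[:, None]
    span = max(float(pos[-1] - pos[0]), 1.0)
    ls0 = max(span / max(pos.size - 1, 1) * 5.0, 1.0)
    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * RBF(ls0, (ls0 / 100.0, span * 10.0))
              + WhiteKernel(0.1, (1e-6, 10.0)))
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                          n_restarts_optimizer=0,
                                          random_state=random_state)
            gp.fit(x, y)
            pred = gp.predict(x)
    except Exception:
        gp, pred = None, np.full_like(y, mean_logit)
    mse = float(np.mean((expit(pred) - af) ** 2))
    return GPSegment(start, end, mse, gp, mean_logit, int(pos.size))


@dataclass
class GPBiasModel:
    """Per-cell local-bias model: fitted GP segments over h1 allele fraction."""

    cell_id: str
    segments: List[GPSegment] = field(default_factory=list)

    @classmethod
    def fit(cls, cell_id: str, positions: Sequence[int], afs_h1: Sequence[float],
            random_state: int = 0) -> "GPBiasModel":
        model = cls(cell_id=cell_id)
        pos = np.asarray(positions)
        af = np.asarray(afs_h1, dtype=float)
        for sl in partition_fragments(pos, af):
            model.segments.append(
                fit_segment_gp(pos[sl], af[sl], random_state=random_state))
        return model

    def predict_local_af(self, position: int) -> LocalAFPrediction:
        """Logistic of the GP posterior mean at ``position``; uninformative
        (0.5, unusable) outside all segments or in an MSE-failed segment."""
        for seg in self.segments:
            if seg.start <= position <= seg.end:
                if not seg.usable:
                    return LocalAFPrediction(position, 0.5, 0.5, False)
                af1 = float(np.clip(expit(seg.predict_logit(position)),
                                    AF_EPS, 1.0 - AF_EPS))
                return LocalAFPrediction(position, af1, 1.0 - af1, True)
        return LocalAFPrediction(position, 0.5, 0.5, False)
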