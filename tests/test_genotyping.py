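"""Joint genotyping: bulk likelihood, phased mixtures, EM, DP posterior."""
import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import comb

from mosaicstr.config import RunConfig
from mosaicstr.genotyping import (CellLocusData, IndividualLocusData,
                                  bulk_mosaic_likelihood,
                                  genotype_posterior_gate,
                                  phased_cell_likelihood, prescan_candidates,
                                  run_joint_em, site_mutant_count_posterior)


class TestPrescan:
    def test_rules(self):
        summaries = [
            {"id": "ref_only", "n_alt_alleles": 0, "mean_cell_depth": 10.0},
            {"id": "shallow", "n_alt_alleles": 1, "mean_cell_depth": 0.8},
            {"id": "good", "n_alt_alleles": 1, "mean_cell_depth": 5.0},
        ]
        kept = prescan_candidates(summaries)
        assert [s["id"] for s in kept] == ["good"]


class TestBulkLikelihood:
    def test_empty_data(self):
        assert bulk_mosaic_likelihood(0, 0) == pytest.approx(1.0)

    def test_matches_quadrature(self):
        val = bulk_mosaic_likelihood(3, 10)
        num, _ = quad(lambda t: comb(10, 3) * t ** 3 * (1 - t) ** 7, 0, 1)
        assert val == pytest.approx(num, abs=1e-12)
        assert val == pytest.approx(1.0 / 11)

    @pytest.mark.parametrize("depth", [5, 30, 200])
    def test_independent_of_alt_count(self, depth):
        vals = [bulk_mosaic_likelihood(r, depth)
                for r in range(0, depth + 1, max(depth // 7, 1))]
        np.testing.assert_allclose(vals, 1.0 / (depth + 1), atol=1e-10)

    def test_quadrature_across_depths(self):
        """Closed form equals adaptive quadrature to 1e-10 up to depth 200."""
        from scipy.special import gammaln

        rng = np.random.default_rng(0)
        for depth in (1, 7, 50, 200):
            for r in sorted(set(rng.integers(0, depth + 1, 4).tolist())):
                log_c = gammaln(depth + 1) - gammaln(r + 1) \
                    - gammaln(depth - r + 1)

                def integrand(t, r=r, depth=depth, log_c=log_c):
                    if t in (0.0, 1.0):
                        t = min(max(t, 1e-300), 1 - 1e-16)
                    return np.exp(log_c + r * np.log(t)
                                  + (depth - r) * np.log1p(-t))

                peak = r / depth if depth else 0.5
                want, _ = quad(integrand, 0, 1, points=[peak], limit=200)
                assert bulk_mosaic_likelihood(r, depth) == pytest.approx(
                    want, abs=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            bulk_mosaic_likelihood(5, 3)


def _cell(read_lik, links, af_h1=0.5, usable=True, cell_id="c"):
    return CellLocusData(cell_id=cell_id, read_lik=np.array(read_lik),
                         hsnp_link=np.array(links), af_h1=af_h1,
                         af_usable=usable)


class TestPhasedLikelihood:
    def test_collapsed_mixture(self):
        # phasing prob 1 for allele0-h1, read carries h1 and matches allele0
        cell = _cell([[0.98, 0.009]], [0], af_h1=0.6)
        ll = phased_cell_likelihood(cell, (0, 1), phase_p=1.0)
        assert ll == pytest.approx(np.log(0.6 * 0.98))

    def test_symmetric_settings_collapse_to_unphased(self):
        """With phasing 0.5 and AF 0.5 the phased value equals the plain
        half-half mixture times the constant haplotype-sampling factor."""
        lik = np.array([[0.9, 0.1], [0.2, 0.7], [0.5, 0.5]])
        linked = _cell(lik, [0, 1, 0])
        unphased = _cell(lik, [-1, -1, -1])
        ll_link = phased_cell_likelihood(linked, (0, 1), 0.5)
        ll_plain = phased_cell_likelihood(unphased, (0, 1), 0.5)
        # constant factor AF = 0.5 per linked read
        assert ll_link == pytest.approx(ll_plain + 3 * np.log(0.5))
        # and the factor cancels between genotypes
        d_link = ll_link - phased_cell_likelihood(linked, (1, 1), 0.5)
        d_plain = ll_plain - phased_cell_likelihood(unphased, (1, 1), 0.5)
        assert d_link == pytest.approx(d_plain)

    def test_matches_bruteforce_four_term_sum(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            lik = rng.uniform(0.01, 1.0, (3, 2))
            links = rng.choice([-1, 0, 1], 3)
            af1 = rng.uniform(0.1, 0.9)
            p = rng.uniform(0.0, 1.0)
            cell = _cell(lik, links, af_h1=af1)
            got = phased_cell_likelihood(cell, (0, 1), p)
            want = 0.0
            for m in range(3):
                lx, ly = lik[m]
                if links[m] == -1:
                    term = 0.5 * lx + 0.5 * ly
                else:
                    af = af1 if links[m] == 0 else 1 - af1
                    # P(allele0 on linked hap) is p for h1, 1-p for h2
                    w0 = p if links[m] == 0 else 1 - p
                    term = af * (w0 * lx + (1 - w0) * ly)
                want += np.log(term)
            assert got == pytest.approx(want, abs=1e-12)

    def test_empty_cell_contributes_nothing(self):
        cell = CellLocusData(cell_id="c", read_lik=np.zeros((0, 2)),
                             hsnp_link=np.zeros(0, dtype=int))
        assert phased_cell_likelihood(cell, (0, 1), 0.5) == 0.0


class TestSitePosterior:
    def test_forced_mosaic(self):
        sp = site_mutant_count_posterior([1.0], [1e-300], mu=0.01)
        assert sp.mosaic_posterior == pytest.approx(1.0, abs=1e-6)

    def test_uninformative_likelihood_returns_prior(self):
        N, mu = 5, 0.2
        sp = site_mutant_count_posterior(np.ones(N), np.ones(N), mu=mu)
        from scipy.stats import binom

        prior = binom.pmf(np.arange(N + 1), N, mu)
        np.testing.assert_allclose(sp.count_posterior, prior, atol=1e-12)

    @pytest.mark.parametrize("N", [1, 2, 4, 6, 8])
    def test_dp_equals_exhaustive_enumeration(self, N):
        rng = np.random.default_rng(100 + N)
        for _ in range(20):
            pm = rng.uniform(1e-3, 1.0, N)
            pg = rng.uniform(1e-3, 1.0, N)
            mu = float(rng.uniform(0.01, 0.4))
            sp = site_mutant_count_posterior(pm, pg, mu)
            post = np.zeros(N + 1)
            for bits in itertools.product([0, 1], repeat=N):
                w = np.prod([mu * pm[i] if b else (1 - mu) * pg[i]
                             for i, b in enumerate(bits)])
                post[sum(bits)] += w
            post /= post.sum()
            assert np.max(np.abs(post - sp.count_posterior)) < 1e-9

    def test_posterior_normalized(self):
        sp = site_mutant_count_posterior([0.5, 0.1], [0.6, 0.9], 0.05)
        assert sp.count_posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_cells_rejected(self):
        with pytest.raises(ValueError):
            site_mutant_count_posterior([], [], 0.1)


class TestGate:
    def test_boundaries(self):
        assert genotype_posterior_gate(0.95)
        assert genotype_posterior_gate(0.90)
        assert not genotype_posterior_gate(0.89)
        assert genotype_posterior_gate(0.6, cutoff=0.5)  # ATAC mode


def _reads_cell(lens, alleles, model, links=None, cell_id="c"):
    from mosaicstr.stutter import stutter_prob_matrix

    lik = stutter_prob_matrix(np.array(lens), np.array(alleles), model)
    if links is None:
        links = [-1] * len(lens)
    return _cell(lik, links, cell_id=cell_id)


class TestJointEM:
    def test_no_signal_limit(self, default_model):
        """Clean homozygous-reference cells: germline posterior concentrates
        on (ref, ref) and mosaic fractions stay near zero."""
        alleles = [10, 11]
        ind = IndividualLocusData(
            individual_id="i",
            bulk=_reads_cell([10] * 40, alleles, default_model, cell_id="b"),
            cells=[_reads_cell([10] * 20, alleles, default_model,
                               cell_id=f"c{i}") for i in range(4)])
        state = run_joint_em([ind], 2, RunConfig())
        hom_ref = state.pairs.index((0, 0))
        assert state.germline_posteriors[0][hom_ref] > 0.99
        assert float(np.max(state.mu[0])) < 0.01

    def test_single_mosaic_cell_detected(self, default_model):
        """One cell carrying a half-VAF mutant allele raises mu and the
        mutant-genotype likelihood for that cell only."""
        alleles = [10, 12]
        germ = [10] * 30
        mutant = [10] * 15 + [12] * 15
        ind = IndividualLocusData(
            individual_id="i",
            bulk=_reads_cell([10] * 60, alleles, default_model, cell_id="b"),
            cells=[_reads_cell(germ, alleles, default_model, cell_id="c0"),
                   _reads_cell(mutant, alleles, default_model, cell_id="c1"),
                   _reads_cell(germ, alleles, default_model, cell_id="c2")])
        state = run_joint_em([ind], 2, RunConfig())
        g_star = state.top_genotype(0)
        assert g_star == (0, 0)
        assert state.mu[0][0, 1] > 0.05
        p_mut = [phased_cell_likelihood(c, (0, 1), state.phase_p[0])
                 for c in ind.cells]
        p_germ = [phased_cell_likelihood(c, (0, 0), state.phase_p[0])
                  for c in ind.cells]
        sp = site_mutant_count_posterior(p_mut, p_germ,
                                         float(state.mu[0][0, 1]),
                                         as_log=True)
        assert sp.mosaic_posterior > 0.99
        assert np.argmax(sp.cell_mutant_posteriors) == 1

    def test_population_frequency_recovery(self, default_model):
        """f recovered within 0.05 across 10 individuals with known truth."""
        rng = np.random.default_rng(9)
        alleles = [10, 11]
        f_true = 0.7
        inds = []
        draws = []
        for i in range(10):
            g = [10 if rng.random() < f_true else 11 for _ in range(2)]
            draws.extend(g)
            lens = [g[int(rng.integers(2))] for _ in range(40)]
            cell_lens = [g[int(rng.integers(2))] for _ in range(20)]
            inds.append(IndividualLocusData(
                individual_id=f"i{i}",
                bulk=_reads_cell(lens, alleles, default_model, cell_id="b"),
                cells=[_reads_cell(cell_lens, alleles, default_model)]))
        state = run_joint_em(inds, 2, RunConfig())
        realized = np.mean(np.array(draws) == 10)
        assert abs(state.f[0] - realized) <= 0.05

    def test_loglik_monotone(self, default_model):
        rng = np.random.default_rng(11)
        alleles = [10, 11, 12]
        inds = []
        for i in range(3):
            lens = rng.choice(alleles, 30).tolist()
            inds.append(IndividualLocusData(
                individual_id=f"i{i}",
                bulk=_reads_cell(lens, alleles, default_model, cell_id="b"),
                cells=[_reads_cell(rng.choice(alleles, 15).tolist(),
                                   alleles, default_model)]))
        state = run_joint_em(inds, 3, RunConfig())
        diffs = np.diff(state.loglik_trace)
        assert np.all(diffs > -1e-8)
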