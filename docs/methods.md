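# Methods

`mosaicstr` detects postzygotic (mosaic) mutations at short tandem repeats
(STRs, microsatellites) in single-cell sequencing data. STRs mutate through
polymerase slippage both in vivo (the mutations of interest) and in vitro
(PCR/WGA stutter artifacts), so the central statistical problem is
separating a true single-cell mutation from a stutter artifact, an
amplification artifact, or a mis-segmented read. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic test bed does and does not demonstrate.

## Read segmentation

Each catalog locus gets a small three-block hidden Markov model:

* **STR block** — one state per motif base, cycling in motif order
  (S_C -> S_A -> S_G for CAG). Emissions follow the per-base error model:
  the expected base has probability `1 - e`, every other base `e / 3`,
  with `e` taken from the read's phred qualities. An observed `N` scores
  0.25 in every state.
* **Interruption block** — per STR position, an insert state (uniform
  emission, self-loop 0.3) and a mismatch state (uniform emission), plus a
  skip transition (S_i -> S_{i+2 mod m}) that plays the role of a
  single-base deletion. We chose transitions over silent delete states
  because silent states complicate Viterbi without changing which
  segmentations are representable at this scale. Entry probability
  `interruption_trans` defaults to 0.01 and is configurable; a small
  grid-search utility (`grid_search_interruption`) can tune it against a
  user-supplied labeled catalog.
* **Flanking block** — a generic uniform state on each side plus the
  locus's known 3 bp reference flanks as dedicated states, which anchor
  the repeat/flank boundary.

The initial STR-to-flank transition is `1/L` with `L = 5` bp for
homopolymers and twice the motif length otherwise. Boundaries come from
the Viterbi path; ties effectively resolve by state order (STR states
precede right-flank states in the argmax), which favors the longer core
at an exact right-boundary tie. Reads whose optimal path never enters the
STR block are the "no repeat" outcome; the caller then projects the
catalog coordinates through the read's CIGAR (the fallback used for large
deletions below the step length — two motif units under the reference
length by default — and for interrupted 4–6 bp-motif loci).

Viterbi is exact, so correctness is checked two ways: exhaustive DFS over
the sparse transition graph on reads up to ~10 bp, and agreement with an
independently implemented decoder (hmmlearn) on 25 bp reads for all motif
lengths, using a constant per-base error rate because that decoder's
emissions cannot vary by position.

## Stutter model and length EM

In-vitro slippage is geometric in whole repeat units: a read matches its
template with probability `1 - u - d`, gains `n` units with probability
`u * rho * (1-rho)^(n-1)`, loses `n` units with `d * rho * (1-rho)^(n-1)`.
A read cannot lose more units than the template has, so that deletion
tail is truncated to zero. Length differences that are not whole unit
multiples round to the nearest unit. Defaults/initializations:
`u0 = d0 = 0.01`, `rho0 = 0.9`, floors `u, d >= 1e-4`, `rho <= 1 - 1e-6`.

`fit_stutter_em` estimates `(u, d, rho)` pooled per sequencing protocol,
plus per-locus length allele frequencies `f`, by EM over a cohort of
individuals with bulk plus single cells. The latent structure per
individual: a germline genotype drawn from Hardy-Weinberg (`f_j^2` or
`2 f_j f_k`), per-cell branches allowing a single-haplotype switch with
total probability `mu_msi = 0.001` per haplotype (fixed during this EM;
branch weights are normalized over targets so the prior sums to one), and
per-read source-allele assignments. The M-step is the exact
complete-data MLE of the geometric family: `u` and `d` are
posterior-weighted insertion/deletion fractions over reads; `rho` is
(stutter events) / (total stutter steps). The observed-data
log-likelihood is non-decreasing (asserted to 1e-8); convergence is a
relative tolerance of 1e-6 with at most 200 iterations. Per-site
refitting is possible but off by default: at single-cell depth a per-site
fit of three parameters is unstable, so the protocol-level fit is reused.

## Candidate alleles and alignment likelihoods

Distinct full-span read cores with at least 2 supporting reads become
candidate alleles (reference always included, pool capped at 8 by
support), padded with 5 bp of reference flank. A read is scored against
an allele under exactly one of three scenarios decided by the length
relation:

* equal length — `(1 - u - d) * prod_i Q(X_i, Y_i)` with
  `Q = 1 - e` / `e / 3` (the same error model as segmentation; the
  agreement score is not separately defined anywhere else);
* read shorter by dL — the geometric deletion mass times the *mean* over
  all `L - dL + 1` deletion placements of the spliced agreement product;
* read longer by dL — the geometric insertion mass times `1/(L+1)` times
  the sum over insertion positions, where the inserted bases are modeled
  as a local duplication: positions within dL of the left edge can only
  copy from the right, within dL of the right edge only from the left,
  and interior positions average both directions with weight 1/2.

The placement sums are computed with prefix/suffix cumulative products
(O(L) per pair) and verified against brute-force enumeration to 1e-12.
The geometric exponent uses dL in repeat units (`dL / L_RU`, rounded, at
least 1).

Mutation type/size/offset comes from comparing mutant and germline
alleles with 4 bp flanks. Indels are left-normalized: the reported offset
is the smallest placement consistent with the common prefix/suffix, which
matches VCF convention; a microhomology flag records when the
inserted/deleted block equals the adjacent sequence. A global pairwise
aligner (match +1, mismatch -1, gap open -2, extend -0.5) backs the
mismatch path when lengths agree but several substitutions exist.

## Amplification bias

**Global.** At germline hSNPs of a common median depth `dp` (sites kept
within +-20% of `dp`), alternative counts are over-dispersed binomial.
The beta-binomial shape parameters come from the standard
method-of-moments estimator on the first two raw moments; a non-positive
denominator means the data are binomial-or-tighter and a "binomial limit"
sentinel is returned instead of nonsense negative shapes.

**Local.** Within one cell, amplification bias is correlated along
amplified fragments. Per chromosome the phased-hSNP allele-fraction
series is partitioned by a two-state Gaussian HMM on logit-AF (state
means at the 25th/75th percentile of the series, shared SD floored at
0.05, switch probability 0.01, Viterbi path; a break is also forced at
inter-hSNP gaps over 1 Mb). Within each segment a zero-mean Gaussian
process with an RBF kernel plus a jointly estimated white-noise nugget is
fitted on logit-AF — the nugget is a numerical necessity absent from the
idealized model, because logits of binomial fractions are noisy.
AFs are clamped to (1e-7, 1 - 1e-7) before the logit so dropout does not
produce infinities. Predictions are the logistic of the GP posterior
mean. Segments whose training MSE on the AF scale exceeds 0.5 are marked
unusable (the AF scale is bounded and comparable across segments, which
is why the filter lives there rather than on logits), and positions
outside any segment predict an uninformative 0.5.

## Joint genotyping

Per locus, the cohort-level EM couples three layers. Population: allele
frequencies `f` over the candidate pool, Hardy-Weinberg genotype priors.
Bulk: the individual's bulk reads scored with the same allele mixture
(the uniform-VAF mosaic likelihood of bulk data has the closed form
`C(depth, r) * B(r+1, depth-r+1) = 1/(depth+1)`, independent of `r`).
Cells: each cell's genotype equals the germline pair except for
single-haplotype mosaic switches with per-target fractions `mu[k -> a]`
(initialized at `mu_msi / (n-1)`, renormalized mixture weights, double
mutations excluded).

Reads covering both the STR and the nearest hSNP (within 500 bp; ties to
the closer then smaller coordinate) contribute a phased term: the joint
probability of (source allele, observed haplotype link) is
`AF_hap * P(allele on hap) * P(read | allele)`, with `AF_hap` from the
local bias model (0.5 when unusable) and a per-individual phasing
probability initialized at 0.5 and re-estimated each M-step from the
posterior-weighted link concordance of dual-covering reads in
heterozygous genotypes. Reads without a link contribute the plain
half-half mixture. Everything is accumulated in log space; the EM runs
at most 15 iterations (tolerance 1e-5) during site calling, since the
stutter parameters are already pooled and the per-locus posteriors
stabilize quickly.

The site-level posterior over the mutant-cell count `L` uses the DP
recursion `M[l, j] = M[l, j-1] * P(D_j | germ) + M[l-1, j-1] *
P(D_j | mut)` with a binomial(`mu`) prior; because the prior puts
`P(L=l) / C(N, l)` on each configuration it is equivalent to independent
Bernoulli(`mu`) indicators, which also gives exact per-cell mutant
posteriors in closed form. `mu` is floored at 1e-6 so `L = 0` is never
absorbing. The mosaic posterior is `1 - P(L=0 | data)`; the genotyping
gate requires 0.9 (0.5 in the sparse-data pseudo-bulk mode).

## Filters and classification

The filter cascade runs prescan (at least one alternative allele, mean
cell depth > 1), the posterior gate, the phasing filters, then the
forest. Four discordance rates are computed from (allele x haplotype)
read-count tables under the convention that the germline allele links h1
and the mutant allele links h2 (h2 is relabeled to the mutant cell's
majority link): bulk discordance, all-cell discordance, amplification
error (germline allele on the mutant haplotype in the mutant cell), and
mutant-cell discordance. Phase-informed calls need all four below 0.1
(strict), mutant-cell VAF >= 0.1 and >= 2 mutant reads; non-phaseable
calls need VAF > 0.25 (strict) and >= 3 mutant reads. An undefined rate
(zero denominator) fails the filter.

Two random forests (500 trees, sqrt features, fixed seed) predict five
classes — amplification error, sequencing error, repeat (stutter),
heterozygous, mosaic — from a 30-feature vector (depth statistics, VAFs,
posteriors, stutter parameters, segmentation diagnostics, phasing rates,
local-AF predictions, quality summaries). The published feature table is
roughly twice as long but is not reproducible from text alone; the schema
here is versioned and extensible, and phase features are sentinel -1 in
the genome-wide model. Ties in the class probabilities break toward the
lowest class index, so a tie never yields mosaic. Training and
evaluation are leave-one-donor-out; labels for the synthetic test bed
come from the simulator truth table. Orthogonal validation uses the
printed one-sided lower-tail binomial rules (validated when `P >= 0.05`
and `k > 0`; larger of the model-derived and 0.5 null retained) and the
two-bulk germline gate (VAF in [0.4, 0.6] or a two-tailed binomial
P > 0.05, in *both* bulks, routes a call to germline).

## Synthetic cohort

The simulator is the primary test substrate and emulates exactly the
structure the caller models: a synthetic reference with catalogued STR
tracts (motifs 1–4 bp, 6–10 reference copies), germline diploid
genotypes drawn from simple population frequencies (70% reference
length, 15% each +-1 unit), a phased hSNP 20 bp upstream of every tract,
geometric stutter at read generation (u = d = 0.01, rho = 0.9 by
default), per-base errors from per-read quality levels (Q25/30/35,
mirroring modern instruments' binned qualities), beta-binomial
allele-specific amplification (alpha = beta = 10), 2% allelic dropout,
Poisson(30) spanning reads per cell-locus with a deep balanced bulk, and
spiked mosaic indels (+-1 or 2 units, one carrier cell, the whole target
haplotype rewritten, i.e. in-cell VAF ~0.5) recorded in a truth table.
Reads carry real alignment records (CIGAR against the synthetic
reference), so the SAM/VCF/BED/FASTA I/O path is exercised end to end; an
in-memory mode bypasses files for unit tests.

What it does **not** emulate: chimeric MDA/PTA artifacts, mapping bias
and multi-mapping, real stutter's locus-dependence (GC, tract length),
coverage waviness beyond the beta-binomial, index hopping, or germline
structural variation. Passing the end-to-end bar (recall >= 0.80 at
precision >= 0.90 over 500 loci / 10 cells / 50 spiked sites, stable
across seeds) therefore demonstrates internal consistency of the model
chain at realistic depths — not performance on real tissue. Problem
sizes in the test suite (500-locus cohorts, 200-locus EM training,
1e5-site moment recovery) were chosen as the smallest sizes at which the
statistical tolerances are comfortably identifiable.

## snATAC adaptation

Sparse snATAC coverage precludes per-cell genotyping, so reads are
deduplicated barcode-aware (groups share barcode + fragment start/end;
only identical sequences are duplicates; the best read by MAPQ, then
mean base quality, then read id survives), pooled per individual into a
pseudo-cell, and genotyped on repeat lengths against the bulk-derived
germline. Retention requires all five rules: posterior > 0.5, > 10
genotyping reads, bulk homozygous with exactly one alternative read
(applied to the matched bulk pool, switchable), no other artifact reads
at the locus, and recurrence in fewer than two individuals. Per-cell
mutation rates are mutations over callable length (loci spanned by at
least one MAPQ >= 20 read with 1 bp on each side), averaged over cells
with nonzero callable length.

## Known limitations

* Diploid autosomes only; no haploid sex-chromosome handling, no CNV.
* One mutant allele per site is reported (the best by site posterior).
* The phasing probability is a single per-individual scalar per locus
  rather than a full per-pair table; with more than two plausible
  alleles this is an approximation.
* Stutter parameters are protocol-level; locus covariates (GC, tract
  length) are deliberately out of scope.
* The simulator's quality model and its single-contig reference are
  idealizations; see above for the full list of unmodeled effects.
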