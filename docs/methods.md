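# Methods

## The model and what it tests

The pipeline targets replicated evolve-and-resequence (E&R) designs with
pooled sequencing: two treatments (selected vs control), `k` replicate
populations each, pooled whole-organism sequencing at an early and a late
generation. Pool-seq yields per-site allele read counts, not genotypes or
haplotypes, so every statistic here is built on counts.

At each biallelic variant the late-generation alt count in sample *i* is
modeled as

    alt_i ~ Binomial(depth_i, p_i),  logit(p_i) = b0 + b1 t_i + u_i,
    u_i ~ N(0, sigma_u^2),

with `t_i` the treatment indicator and one random intercept per replicate
population (six levels in the 3+3 design). The random effect absorbs the
two extra-binomial noise sources of the design - genetic drift across
replicates and pool-construction sampling - while `b1` captures divergence
that is *consistent across replicates*. The marginal likelihood integrates
each `u_i` out by adaptive Gauss-Hermite quadrature (15 nodes by default;
the integrand's mode and curvature are found per observation by a damped
Newton step, which makes the quadrature accurate even for sharply peaked
high-depth sites). Estimation is a batched Levenberg-damped Newton ascent
vectorized across variants, with the score and observed information taken
from quadrature posterior moments (Louis' identity); convergence is
declared at a score sup-norm below 1e-8, with at most 200 iterations. The
reported test is the two-sided Wald z on `b1`. `sigma_u` is constrained
non-negative (the likelihood is even in `sigma_u`, so the optimizer works
on the real line and reports the absolute value); when the estimate sits at
the zero boundary the standard error comes from the fixed-effects (plain
binomial GLM) information instead of the full 3x3 inverse. Quasi-complete
separation (|b1| > 12 or an unusable standard error) is flagged and the
p-value replaced by a likelihood-ratio test against the no-treatment model
fitted with the same machinery.

Single-site fits agree with an independent dense-grid-integration oracle to
at least six significant figures in the estimates and three in the p-value
(tested), and collapse exactly to the fixed-effects GLM when the variance
estimate hits zero (tested against statsmodels).

## Permutation FDR

P-values from a 6-observation mixed model cannot be trusted at face value
(see Limitations), so significance is calibrated empirically: the model is
refit under every balanced relabeling of the six late-generation samples -
C(6,3)/2 - 1 = 9 for 3+3, with group-label swaps identified - and, on a
grid of thresholds `P` (the distinct observed p-values),

    FDR(P) = [mean over relabelings of #{p_perm < P}] / #{p_obs < P}.

The SDV threshold is the largest `P` with FDR(P) < 0.05; both counts use a
strict `<`. The curve is not monotonized by default; a q-value-style
cumulative-minimum option exists. Because driver signal survives partially
under relabeling (a 2-vs-1 split retains a third of a consistent shift),
the numerator is inflated at spiked loci and the procedure errs
conservative - with nine permutations it is deliberately stringent.

## Count-level QC

Filters run in a fixed order on counts merged across all samples
("VarRef"): (1) the error threshold is the lower 0.75-quantile of the
third-largest allele count per site; sites whose third allele exceeds it
are dropped, and sites whose merged minor count does not exceed it are
dropped; (2) merged depth must strictly exceed 10x and not exceed the lower
0.95-quantile of merged depth at biallelic sites; sites under 10x in every
sample of a generation cohort are dropped; (3) a site is high-confidence
when the lower bound of the two-sided 99.73% binomial CI for its minor
allele clears zero in at least one sample. All quantiles are lower
(type-1) empirical quantiles - order statistics, appropriate for integer
counts. The CI is Clopper-Pearson by default (exact; a zero count gives a
bound of exactly 0); note that with an exact CI any single minor read
yields a positive bound, so the filter's effective bite comes from the
merged minor-count rule - Wilson and Wald (normal, z = 3) bounds are
options, and the Wald bound is the variant that meaningfully thins
low-count sites. The two data-derived cutoffs are recorded in the filter
report and can be re-applied (`frozen=`), which makes the chain a fixed
point on its own output; re-estimating a quantile on already-truncated
output would necessarily move it.

## diffStat and consistency statistics

diffStat forms the nine signed differences between the three selected and
three control replicate frequencies; if all nine share a strict sign the
score is the minimum absolute difference, else 0. A zero difference has no
direction and breaks consistency. (The score's literal definition as
abs(min(...)) misbehaves for mixed signs; restricted to direction-consistent
variants the two definitions coincide, and the all-variants convention here
reports 0 for inconsistent ones.) Between-generation consistency applies
the same sign rule to per-replicate changes within one treatment, binning
the minimum magnitude in 5% bins for the treated/control ratio histogram;
an empty control bin reports a missing ratio.

## Window scan and blocks

Pooled data carry no haplotypes, so linked selection is detected spatially:
each arm is tiled with half-open windows (0-based internally; TSV output is
1-based, BED native); a window with `n` variants and `s` SDV is scored by
the upper tail P(X >= s) of Hypergeometric(N, S, n) with per-arm totals N
and S; empty windows are skipped. Multiple testing is adjusted genome-wide
(Benjamini-Hochberg by default; Storey q-values with a lambda-grid median
pi0 optional). Significant windows that overlap or abut merge into maximal
blocks; each block nominates the SDV with the smallest model p (ties: all)
and its host gene(s), or both flanking genes for intergenic variants.
Window and step are free parameters; a sensible choice keeps tens of
variants per window, so sparse simulated genomes (1 locus per 10 kb) use
500-kb windows where a dense empirical study would use 50 kb. A
multi-scale mode scans several window/step pairs and intersects the
resulting block intervals, reporting only regions robust to the window-size
choice.

## Enrichment and PBS

Gene scores are the minimum per-SNP p over the gene body plus a flank
(default 500 bp, half-open at the flank edge; overlapping genes share
SNPs). The resampling test counts query-set genes in the lower `tail`
(default 5%) of gene scores and calibrates against draws of random SNP sets
matching the observed tail-defining SNP count, each gene counting once per
draw regardless of how many of its SNPs were sampled - this is what removes
gene-length bias. Empirical p-values use the add-one estimator
(1 + #{null >= obs})/(1 + n_sims), bounded below by 1/(1 + n_sims), with
Bonferroni across sets.

FST between two populations uses the Reynolds (1983) ANOVA estimator in
mean-square form with the n_c small-sample correction, sample sizes in
chromosomes; negative estimates clip to 0 (raw values are returned
alongside). Branch lengths are T = -log(1 - FST) (natural log; FST = 1 is
rejected as an infinite branch) and PBS = (T_HL + T_HO - T_LO)/2. Tail
enrichment uses the realized tail fraction as the binomial baseline
(candidates included; a strict exclude-candidates variant is a flag) and an
exact two-sided binomial test under the minimum-likelihood convention
(doubling-the-smaller-tail optional). Ortholog joining unions per-source
calls after dropping, within each source, fly genes above a fan-out limit
(default 1 human ortholog), then removes pairs contradicted by another
source that maps the same fly gene; silence is not conflict.

## The simulator

The generator emulates the study design: `n_lines` isofemale founder lines
x `haploids_per_line` haplotypes (default 27 x 4 = 108); per-site founder
frequencies from a 1/f spectrum truncated to [1/108, 0.5] (uniform
optional); carrier lines or haplotypes chosen as the top-ranked rows of a
latent Gaussian field, AR(1) along the chromosome. A site is line-structured
with probability `line_identity` (default 0.75, modeling partial line
homozygosity; at 1.0 every founder frequency is a multiple of 1/27). The
AR(1) correlation length (`founder_ld_scale`, default 2 Mb) sets how fast
founder LD decays with distance: isofemale lines become homozygous within a
few generations of capture, after which recombination no longer reshuffles
them, so their haplotype blocks are megabase-scale. This founder LD -
shared by all replicates - is what makes hitchhiking during the experiment
consistent across replicates and spatially local, the signal the block scan
exists to find.

Each replicate is a diploid Wright-Fisher population (constant `ne`):
parents are drawn proportional to multiplicative fitness across driver loci
(1, 1+hs, 1+s per genotype; active only in selected replicates from the
onset generation, default 1), and gametes recombine with per-gap crossover
fractions from Haldane's map at `recomb_rate` per bp (free recombination
optional). Sequencing samples `pool_individuals` diploids without
replacement (both chromosomes enter the pool), draws depth per site from a
negative binomial with mean `depth_mean` (80x default, in the study's
26-99x range) and shape `depth_dispersion` (10; infinite shape gives
Poisson), then binomial reads with per-read miscall probability
`error_rate` (0.001) to a uniformly random other base.

A second founder mode, `linkage_equilibrium`, seeds each replicate with
independent Bernoulli(f) alleles per chromosome - no shared founder LD at
all. It exists because calibration benchmarks on "unlinked loci" need loci
that are *statistically independent*, not merely free-recombining: with a
shared 108-haplotype founder pool, background LD between null sites and
drivers (r^2 of order 1/27 at line level) produces a replicated correlated
response to selection at null sites that no label permutation can see, and
a false-discovery benchmark against a known driver set would conflate that
real treatment response with estimation error.

Mean driver trajectories reproduce the deterministic one-locus recursion
p' = p + s p (1-p)(p + h(1-2p)) / wbar (tested at Ne = 10,000 over 200
replicates), and neutral sites drift as a martingale with variance
pq (t+1)/(2 Ne) - the +1 is the sampling round that founds each cage from
the founder pool.

## What the benchmarks show - and what they do not

The false-discovery benchmark (10 spiked experiments, 2,000
linkage-equilibrium loci, 200 drivers at s = 0.15, Ne = 1,000, 80x) gives a
pooled realized false-discovery proportion of ~4% at the FDR < 5%
threshold. This validates the permutation calibration under independent
loci. On real data - and on simulations with isofemale-line founders - SDV
additionally include *hitchhikers*: variants in LD with drivers whose
divergence is genuinely treatment-caused. The block scan exists precisely
because such calls cluster; they are not controlled (or controllable) by
the permutation FDR, and a driver-vs-SDV comparison on linked genomes will
show a much higher nominal "false" fraction that is really linkage, not
miscalibration.

## Known limitations

* **Wald p-values are anti-conservative.** With six observations and an
  estimated random-effect variance, maximum-likelihood Wald (and LRT)
  p-values from this model are inflated in the tail whenever true
  overdispersion is present (about twice the nominal rate at p < 0.05 in
  simulations from the model's own generative law). This is a property of
  the statistic, not the implementation (which matches a dense-grid oracle
  to high precision). Downstream error control must come from the
  permutation FDR; null p-value histograms from this pipeline should not
  be expected to pass strict uniformity checks.
* **QC can discard true targets.** The quantile-derived tri-allelic rule
  drops roughly 5-10% of sites at typical depths and error rates (two
  same-base error reads suffice at a threshold of 1); a selected site lost
  there is invisible to everything downstream.
* **Top-variant nomination is a heuristic.** Within a sweep block, dozens
  of linked sites have nearly equal true divergence; with three replicates
  per group the smallest p among them is noisy, and the nominated top
  variant is the actual driver only most of the time (~7/8 of blocks in the
  recovery benchmark when the driver survives QC).
* The simulator draws founder allele placements from a stationary copula
  rather than a coalescent; its LD is summarized by one correlation length.
  No new mutation, no epistasis, no demography beyond constant Ne, no
  read-level artifacts (mapping bias, PCR duplicates); indel alleles are
  accepted downstream but not simulated.
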