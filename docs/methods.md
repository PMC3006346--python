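# Methods

## The analysis

`probmsc` re-implements, as a tested pipeline, the nuclear multilocus
analysis that established the deep speciation of African forest and savanna
elephants. Five proboscidean taxa are compared: forest elephant (F,
*Loxodonta cyclotis*), savanna elephant (S, *L. africana*), Asian elephant
(A, *Elephas maximus*), woolly mammoth (M, *Mammuthus primigenius*) and the
American mastodon (O, *Mammut americanum*) as outgroup. The data design is
hundreds of short, unlinked, anonymous amplicon loci (375 loci, mean 106 bp)
with one diploid individual per elephantid taxon — two chromosomes each —
and a single error-prone haploid mastodon consensus.

The pipeline stages are:

1. **Divergent-site calling** (`sites.call_divergent_sites`). An alignment
   column with exactly two observed alleles across the nine sampled
   chromosomes is a divergent site; each elephantid taxon contributes a
   diploid genotype (0/1/2 copies), the mastodon a haploid call. Loci with
   more than three columns polymorphic *within the elephantids* are dropped
   entirely: polymorphism of that density in an ~106-bp amplicon is the
   signature of co-amplified paralogs, not of diversity.
2. **Polarization** (`sites.polarize`). The mastodon allele defines the
   ancestral state; every elephantid genotype becomes a derived-allele
   frequency f in {0, 1/2, 1}. Sites without a usable mastodon call are
   flagged and excluded from polarized analyses. Polarizing twice equals
   polarizing once.
3. **Recurrence filter** (`sites.filter_recurrent`). Sites whose derived
   allele appears on both sides of the African/Eurasian split in
   configurations that realistically require recurrent mutation or error are
   removed before the descriptive analyses (but *not* before demographic
   fitting, whose model accommodates them). Two rules are provided:
   * `segregating-both-sides` (default): derived allele heterozygous in at
     least one African and one Eurasian taxon.
   * `two-mutation`: flags every cross-side pattern in which neither side is
     fully derived. Rationale: with at most one lineage surviving
     discordantly past the African/Eurasian split, the branches available to
     a single mutation subtend either a within-side set or that stray
     lineage together with the *entire* other side; any other cross-side
     pattern needs two mutations. This is a strict superset of the default
     rule.
4. **Divergence and heterozygosity** (`divergence`). For taxa x, y the
   divergence is the expected-mismatch sum over polarized complete sites,
   sum of f_x(1-f_y) + f_y(1-f_x) — the probability that one chromosome
   drawn from each taxon differs. Within-taxon heterozygosity is the count
   of heterozygous genotypes. Everything is reported relative to
   savanna-Asian divergence t_SA, which therefore has zero uncertainty.
   Fractional (expected-mismatch) counting rather than integer site counting
   is used throughout so that heterozygous genotypes contribute their
   sampling probability, matching the fractional class totals the same
   machinery produces in the ILS table.
5. **Relative-rate tests** (`divergence.relative_rate_test`). Tajima-style:
   n_x = sum f_x(1-f_y) counts derived alleles specific to x since the x/y
   split; the statistic (n_x - n_y)/(n_x + n_y) should be zero under equal
   rates, with z and two-sided p from the weighted jackknife. "Normalized
   by the total number of divergent sites" admits two readings — restricted
   to the pair's lineage-specific sites or global over all divergent
   sites; the pairwise form is the default (the z is invariant to the
   choice up to the jackknife's weighting, since the normalizer only
   rescales), with the global form selectable.
6. **ILS site classes** (`ils`). For an ordered triple (1, 2, 3) — member 3
   may be the merged sister clade "Eurasian" (A+M) or "Loxodonta" (F+S),
   with merged frequency the chromosome-weighted mean — each site
   contributes frequency products to seven classes: e.g. a "12" site where
   1 and 2 share the derived allele to the exclusion of 3 contributes
   f1 f2 (1-f3). Classes "13" and "23" cluster a non-sister pair and
   diagnose incomplete lineage sorting. The headline statistic is the ratio
   of (13+23)/t_SA between the (S, F, Eurasian) and (A, M, Loxodonta)
   triples; a one-sided p for exceeding unity is computed on the log-ratio
   and a two-sided p on the rate difference, both by weighted jackknife.
7. **Weighted jackknife** (`jackknife`). The only uncertainty engine for the
   descriptive statistics. Loci are the resampling blocks; because they
   carry unequal numbers of divergent sites, the delete-m_j jackknife of
   Busing, Meijer & van der Leeden (1999) is used: with n sites over g
   loci, h_j = n/m_j, pseudo-values h_j θ̂ - (h_j - 1) θ̃_j, and variance
   (1/g) Σ (pseudo_j - θ̂_J)² / (h_j - 1). With equal block sizes this
   reduces exactly to the classical delete-one jackknife (tested). Loci
   with zero divergent sites carry no weight and are skipped.
8. **Neighbor-Joining tree** (`njtree`). Saitou-Nei agglomeration on the
   normalized divergence matrix with the Studier-Keppler Q-matrix.
   Determinism matters for testing, so Q-ties break on the lowest
   (row, col) index. Negative branch lengths are clamped to zero with the
   deficit moved to the adjacent branch. Support comes from a site
   bootstrap (resample sites with replacement, rebuild matrix and tree,
   count bipartitions). The distance model is the package's own normalized
   expected-mismatch divergence — a documented divergence from distance
   corrections a general-purpose phylogenetics program would offer.

## The demographic model and simulator

The species tree is fixed: (((F,S),(A,M)),O), with instantaneous splits and
constant population sizes per interval. Everything is parameterized in
mutation units, matching how multilocus coalescent inference is reported:

* τ = T·µ, a split time times the per-year mutation rate; the model carries
  τ_FS, τ_AM, τ_LoxEur (African-Eurasian) and τ_root (elephantid-mastodon);
* θ = 4Nµg, the scaled diploid size of each interval (tips θ_F, θ_S, θ_A,
  θ_M; ancestral θ_FS, θ_AM, θ_LoxEur, θ_root); θ equals the expected
  per-site heterozygosity of two chromosomes drawn from that interval.

Within an interval, each lineage pair coalesces at rate 2/θ, so k lineages
wait Exp(k(k-1)/θ); lineages merge into the parent interval at each τ. The
simulator (`simulate`) draws a genealogy per locus, then drops mutations as
a Poisson process (branch length × locus length expected events) either
under infinite sites (each mutation gets a fresh column; a complete mutation
ledger is kept so tests can compare called sites against planted truth) or
under JC69 (per-column evolution with equal exchange rates, allowing
recurrent hits). Time conversions to years and diploid N happen only at
reporting time through g = 31 years/generation and a user-supplied µ — the
mutation rate is poorly measured for elephantids and is deliberately not a
fitted quantity.

Default parameter values are the study's fitted point estimates
(τ_FS = 0.00135, τ_AM = 0.00131, τ_LoxEur = 0.00220; θ_F = 0.00238,
θ_S = 0.00068, θ_A = 0.00113, θ_M = 0.00093, θ_FS = 0.00263,
θ_AM = 0.00181, θ_LoxEur = 0.00259). Three quantities the study does not
pin down were fixed once:

* τ_root = 0.009 and θ_root = 0.00259: the 24–30 Mya fossil window for the
  elephantid-mastodon split, taken at its ~27 Mya midpoint under the
  reference µ = 3.33e-10/year implied by calibrating τ_LoxEur = 0.00220 to
  the 6.6 Mya midpoint of the 4.2–9.0 Mya African-Eurasian window; the
  root-interval size is set to the African-Eurasian ancestral size. These
  only matter for the mastodon branch (fixed-difference counts), which no
  fitted quantity depends on.
* Locus lengths: 50 + Poisson(56), i.e. mean 106 bp with a 50-bp minimum —
  only the mean is documented for the real amplicons; the minimum reflects
  that primer design needed ≥90 bp alignments.
* Mastodon damage rate 0.05: each mastodon C→T and G→A flips independently
  with this probability, emulating cytosine-deamination errors in the
  1-fold shotgun consensus. The value was chosen so that roughly 62% of
  apparent mastodon-elephantid divergent sites are artifacts, matching the
  observation that only 38% of such sites validated by PCR while the
  mastodon call at elephantid-polymorphic sites was always confirmed — the
  property (ancestral-allele calls robust, absolute mastodon divergence
  unusable) that the damage channel exists to reproduce.

What the generator deliberately does not emulate: read-level coverage and
consensus errors in the elephantid sequences, missing data (every locus has
all nine chromosomes), recombination within loci, gene flow after splits,
linkage between loci, and paralogous co-amplification. Consequently a
passing test shows the *estimators* behave correctly under the published
model's assumptions — it cannot certify robustness to those real-data
pathologies, with one exception: the mastodon damage channel, which is
explicitly simulated and shown not to disturb polarization.

## Demographic inference

The original analysis fit the model by Bayesian MCMC over per-locus gene
trees (MCMCcoal). This package deliberately replaces that with a composite
likelihood over the joint polarized site-pattern spectrum, because the
quantities of scientific interest are the τ and θ ratios, which the
spectrum constrains directly:

* A site's pattern is its derived-copy count per elephantid taxon,
  (n_F, n_S, n_A, n_M) ∈ {0,1,2}⁴. Under infinite sites the per-site
  probability of a pattern equals the expected genealogy branch length
  subtending exactly that configuration.
* Those expected lengths are estimated by Monte Carlo: simulate genealogies
  of the eight elephantid chromosomes (the mastodon and the root interval
  never enter), accumulate branch lengths by subtended pattern. A frozen
  random stream (common random numbers) makes the objective a deterministic
  function of the parameters.
* The objective is the multinomial log-likelihood over all aligned bases,
  with monomorphic columns and the fixed-derived class (2,2,2,2) collapsed
  into one complement category. The collapse removes the two root
  parameters from the problem entirely — the published analysis found them
  unstable for the same reason (mastodon error) — leaving ten parameters:
  three τ and seven θ.
* Optimization: bounded Powell search over (τ_LoxEur, τ_FS/τ_LoxEur,
  τ_AM/τ_LoxEur, θ…) — the ratio parameterization enforces split-time
  ordering — with seeded restarts (default 3), the first started from
  method-of-moments values (tip θ from heterozygosity rates, τ from
  pairwise divergences). Powell was chosen over simplex search after
  measuring ~3× fewer objective evaluations at equal final objective on
  this surface. Search bounds mirror the study's prior windows (T_LoxEur
  4.2–9.0 Mya, T_AM 3.0–8.5, T_FS 0.5–9, mapped through the reference µ;
  θ ∈ [0.0002, 0.008], spanning savanna-to-forest diversity with margin).
* Uncertainty: a weighted jackknife over ~20 blocks of loci, each block
  refit warm-started from the full optimum; 90% intervals are ±1.645
  jackknife SEs. These are frequentist standard-error intervals, not
  posterior credible intervals — a semantic difference from the original
  analysis that the tests account for by checking coverage of known
  simulated truths rather than interval equality. Delete-one-locus
  refitting (375 refits of an MC objective) would cost two orders of
  magnitude more for no inferential gain; grouped blocks stay within the
  same delete-m_j theory.

The fit consumes the *unfiltered* polarized table: recurrent-looking sites
stay in (deep-coalescing configurations are part of the model), mirroring
the original choice to feed MCMCcoal the unfiltered data. On simulated
input the fit also uses uncapped site calls: the three-polymorphic-columns
locus drop is a paralog guard, and simulated loci contain no paralogs —
applying it would discard the most variable ~10% of loci and bias τ and θ
estimates 15–20% low (measured). Real amplicon data should keep the guard
at calling time; its 375 published loci are already the post-guard set.

Numerical details: MC pattern probabilities are floored at 1e-9 inside the
log; 2,000 genealogy replicates per objective evaluation by default (the
MC noise is frozen by the common random numbers, so it perturbs the
optimum's location by less than the sampling noise of 375 loci); fits with
fewer than ~50 loci are possible but spectrum noise dominates.

## Absolute calibration

Split-time ratios become years only through the fossil record:
T_X = (τ_X/τ_LoxEur) × T_LoxEur with T_LoxEur ∈ [4.2, 9.0] Mya. The
calibration multiplies a ratio interval through the fossil window
(`divergence.calibrate_absolute`), e.g. a ratio lower bound of 0.45 gives
0.45 × 4.2 ≈ 1.9 Mya as the earliest forest-savanna split consistent with
both uncertainties. θ converts to diploid N as θ/(4µg) with g = 31 and a
user-supplied µ.

## Validation strategy and problem sizes

Every estimator is checked against an independent oracle: closed-form
pairwise coalescent path lengths (divergence table), the (2/3)e^(-2Δτ/θ)
triplet-discordance formula and exponential waiting-time distributions
(simulator), msprime under a matched demography (two-sample KS on pairwise
coalescence times), dendropy (NJ topologies and newick round trips),
explicit delete-one enumerations (jackknife and both p-value machineries),
the simulator's own mutation ledger (site calling), and
parameter-recovery/coverage experiments at the fitted values (inference).

Routine test runs use 60–800 loci and 10⁴ genealogy replicates; the
parameter-recovery experiment fits ten replicate 375-locus datasets with a
single moment-started Powell run each, and the acceptance script runs the
full pipeline (1,000 bootstrap replicates, 20 jackknife fit blocks) on one
375-locus dataset. These sizes give Monte-Carlo bands comfortably tighter
than the effects being tested while keeping the whole suite inside a few
minutes of CPU.

## Known limitations

* The composite likelihood ignores linkage between sites within a locus;
  its point estimates are consistent but its curvature understates
  uncertainty, which is why all intervals come from the locus-level
  jackknife instead.
* No gene flow, population-size change within intervals, or recombination:
  the model is the published one, and the original authors' caveat applies
  here too — post-split gene flow would push the true initial divergence
  older, not younger.
* Heterozygosity from a single diploid individual per taxon cannot separate
  taxon-level diversity from inbreeding in that individual.
* The damage channel models strand-symmetric C/G→T/A flips only; real
  ancient-DNA damage is end-biased within reads, which is invisible at
  consensus scale.
* With two chromosomes per taxon the site-frequency information per locus
  is minimal; θ estimates for tip taxa lean heavily on total
  heterozygosity, and the ancestral θs on the rare deep-sharing classes,
  which is why their jackknife intervals are wide.
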