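# Methods

This note documents the statistical models implemented in `sealpop`,
the defaults and why they were chosen, what the synthetic generators
emulate, and the numerical decisions a user auditing results will want
to know.

## Genetic distances

**Tamura–Nei + Γ (mtDNA).** For an aligned pair, positions where either
sequence carries N, a gap, or any other ambiguity symbol are excluded
pairwise. From the remaining sites we count the A↔G transition
proportion P₁, the C↔T transition proportion P₂ and the transversion
proportion Q, and estimate base frequencies g_A…g_T from the two
sequences pooled (the classic pairwise convention; an alignment-wide
option is available on `pairwise_sequence_distances`). With
g_R = g_A + g_G, g_Y = g_C + g_T and coefficients

    k1 = 2 g_A g_G / g_R,   k2 = 2 g_T g_C / g_Y,
    k3 = 2 (g_R g_Y − g_A g_G g_Y/g_R − g_T g_C g_R/g_Y),

the distance is d = k1·f(w₁) + k2·f(w₂) + k3·f(w₃), where
w₁ = 1 − P₁/k1 − Q/(2 g_R), w₂ = 1 − P₂/k2 − Q/(2 g_Y),
w₃ = 1 − Q/(2 g_R g_Y), and f(w) = −ln w without rate variation or
f(w) = α (w^(−1/α) − 1) under gamma-distributed rates with shape α.
This is the continuous-gamma closed form; a discrete-category count
(K = 4 in the conventions of likelihood phylogenetics software) is
recorded as metadata only, because the discrete approximation plays no
role in the pairwise formula. The implementation is cross-checked in
the test suite against `ape::dist.dna(model = "TN93", gamma = α)`.
Defaults follow the two mtDNA fragments the survey design uses:
α = 0.25103 for COI and α = 0.164 for the control region. If a w-term
falls to zero or below (saturation) the pair raises an error naming the
sequences; an optional cap substitutes a configured maximum, because a
silent cap would distort downstream permutation statistics.

**Microsatellite genotype distances.** Two integer metrics over
unordered diploid allele pairs, summed over the loci where both
genotypes are called (pairwise deletion): the 0–4 single-locus scheme —
0 for (ii,ii) or (ij,ij), 1 for (ii,ij) or (ij,ik), 2 for (ij,kl),
3 for (ii,jk), 4 for (ii,jj) — which feeds the K_ST test, and the
number-of-different-alleles count 2 − |multiset intersection|, which
feeds the microsatellite AMOVA. The allele-count metric satisfies the
triangle inequality; the 0–4 scheme is a semimetric only
(d(ii,jj) = 4 exceeds the 1 + 1 path through ij), which is harmless for
the rank-type uses it is put to but worth knowing.

## Diversity statistics

Observed heterozygosity is the fraction of heterozygous genotyped
individuals; expected heterozygosity uses Nei's unbiased estimator
(2n/(2n−1))(1 − Σp²). The Hardy–Weinberg test is a Monte-Carlo exact
test: the statistic is the conditional probability of the genotype
array given its allele counts, the null re-pairs the observed allele
pool uniformly, and p counts replicates no more probable than the
observed array with the (1+b)/(1+n_perm) rule; a one-sided
homozygote-excess p (fewer heterozygotes than the null) is reported
alongside, since drifted isolates and null alleles both show up in that
direction. Linkage disequilibrium uses the genotypic G
(log-likelihood-ratio) statistic on the two-locus genotype table, with
a null that permutes one locus's genotypes among individuals; the
permutation stream operates on sorted genotype codes so the p-value is
exactly invariant to individual input order under a fixed seed.
Bonferroni corrections divide the family α by loci × sites (HWE) or
locus pairs × sites (LD); reported thresholds are rounded to a stated
number of significant figures while decisions use the unrounded value.

Allelic richness is standardized by rarefaction over **individuals**
(genotype draws, matching the way standardized-richness tools treat a
"sample"): Â_N is the mean over subsample replicates of the per-locus
count of distinct alleles, averaged over loci, with loci missing from a
subsample renormalized away. For complete data the exact expectation is
hypergeometric at the individual level — an allele carried by t of n
individuals is missed with probability C(n−t, N)/C(n, N) — and the test
suite checks the Monte-Carlo mean against that closed form (the
gene-level 2N-of-2n approximation is biased by a few hundredths at
survey-like counts and is checked only loosely). Richness differences
between units are tested by pooling the two units and re-splitting at
observed sizes.

The duplicate screen flags pairs differing by at most one allele
(counted per allele over mutually called loci) as putative resamples of
one animal; the pipeline drops flagged redundancy before any genetic
stage, keeping the first-seen genotype (optionally the one with fewest
missing loci).

## Between-site structure

Weir & Cockerham's (1984) θ is computed from the per-allele variance
components a (among populations), b (among individuals within
populations) and c (within individuals), combined across alleles and
loci as a ratio of sums Σa/Σ(a+b+c) — not an average of per-locus
ratios — which stabilizes weakly polymorphic loci. Negative θ (and
negative σ²_a in AMOVA) are reported as computed; flooring at zero is a
display choice left to callers. Significance permutes individuals
between the two sites at observed sizes.

The AMOVA is the one-level Excoffier–Smouse–Quattro decomposition of
squared pairwise distances: SS_total = (1/N) Σ_{i<j} d²ᵢⱼ over all
pairs, SS_within the same within sites, σ²_within = SS_within/(N−k),
σ²_among = (MS_among − σ²_within)/n₀ with the usual unequal-size
coefficient n₀, Φ_ST = σ²_a/(σ²_a + σ²_b), and significance by
permuting individuals among sites (default 16,000 permutations).
Singleton sites are excluded with a recorded warning. mtDNA AMOVAs use
TN93+Γ matrices (α per region); microsatellite AMOVAs use the
allele-count-difference matrices.

## The K_ST panmixia test

K_i is the mean distance over unordered within-site pairs; K_S weights
the K_i by sample size nᵢ/Σn (the (nᵢ−1)-weighted variant found in part
of the literature is available via `weights="hbk"`); K_T is the mean
over all pairs pooled; K_ST = 1 − K_S/K_T. The test is one-sided (large
K_ST indicates differentiation; negative K_ST means excess within-site
diversity, not structure). When the number of label arrangements
C(n, n₁) is at most 20,000 the null is enumerated exhaustively and p is
the exact fraction of arrangements at least as extreme, observed
included; otherwise Monte-Carlo with the (1+b)/(1+n_perm) rule, default
5,000 permutations. A matrix with K_T = 0 makes the statistic
undefined; such pairs are returned flagged degenerate with p = 1
(panmixia trivially non-rejectable). The screen tests every usable site
pair per marker independently, applies no multiplicity correction to
the decisions (raw p > α pairs become edges; a Bonferroni-adjusted
decision column is reported for comparison), and returns the connected
components of the resulting graph as panmictic groups.

## Telemetry

Distances are great-circle (haversine, R = 6371.0088 km), anchored at
the capture location, which doubles as the breeding site. The speed
filter enforces the stated plausibility rule only — implied speed
between consecutive retained fixes ≤ 2 m/s — by greedy removal of the
point whose deletion most reduces the violation count (ties: larger
maximum adjacent speed, then later timestamp), recomputing speeds after
each removal; the output satisfies the constraint exactly and the
filter is idempotent. The full angle-and-distance Argos filtering
family is deliberately out of scope.

Seasons are calendar months in UTC: December–May ice-bound,
June–November open-water. The seasonal comparison uses the absolute
difference of season means as its statistic — permutation-equivalent to
the t statistic under equal variance, avoiding a pooling choice — with
labels permuted at observed per-season counts; a season with no data
yields NA. Haulout series are hourly dry fractions; days with more than
4 of 24 hourly values missing are excluded and gaps are never imputed.
Per retained day the mid-range is (min + max)/2, and the circadian
summary reports, per hour of day, the share of days strictly exceeding
their own mid-range (so a constant day exceeds nowhere), plus the
longest consecutive fully-wet run and the minimum dry minutes in any
hour. The exceedance summary is invariant to uniform positive scaling
of a day's values when the daily minimum is zero, but not to adding a
constant — the mid-range shifts with it.

## Synthetic generators

All generators are pure functions of (spec, seed); per-site/locus
sub-streams are derived deterministically so partial regeneration is
reproducible.

**Genotypes.** An F_ST-targeted Dirichlet island model rather than a
coalescent: per locus an ancestral frequency vector p is drawn from a
flat Dirichlet, each site's vector from Dirichlet(p(1−F)/F) — which
makes the among-site variance of an allele's frequency exactly
F·p(1−p), the quantity θ estimates — and genotypes are two independent
allele draws per individual (HWE within sites). Migration rates convert
through the infinite-island equilibrium F = 1/(1 + 4Nm). The bundled
survey emulation uses 11 sites × 9 loci × 8 alleles in three groups:
nine Arctic sites at F = 5·10⁻⁴ (Nm ≈ 500 — panmixia by construction,
since no test at survey sample sizes can resolve it), a Baltic-like
satellite at F = 0.012 (Nm ≈ 20, inside the tens-of-migrants band that
still prevents strong differentiation), and a Saimaa-like isolate at
F = 0.65, chosen so that pairwise θ against other sites lands around
0.3, the level reported for landlocked ringed-seal isolates.

**mtDNA.** A random root sequence is mutated at disjoint position sets
(a fixed number of substitutions per haplotype) to create a shared pool
plus per-site private haplotypes; sites draw haplotype frequencies from
a skewed Dirichlet so one or two haplotypes dominate, and an
isolate option deterministically places all but one individual on a
single private haplotype (≥ 90% of the site's mass). Fragment lengths
default to the two mtDNA windows the survey design trims to (475 and
476 bp).

**Movement.** Winter fixes are isotropic Gaussian around the capture
site (default SD 20 km); summer fixes sit at distance
~Normal(800, 150) km along a persistent random bearing; every fix gets
isotropic Argos-like noise (default 2 km). Kilometres convert to
degrees by a local equirectangular projection at the capture latitude —
a generation-side simplification only; analysis always uses great
circles. Optional injected points displaced 500 km one hour after a
fix provide constructed speed-rule violations. Haulout series elevate
the dry fraction inside a daily window (default 04–19 h) with Gaussian
noise clipped to [0, 1].

**What the generators do not emulate** — and hence what passing tests
do not establish about field data: linkage between loci, null alleles
and genotyping error, selection and demographic history (the Dirichlet
drift has no time axis), within-site relatedness structure,
heteroscedastic Argos location classes, sea-ice geometry constraining
movement, and transmitter duty-cycle gaps. Tests on these fixtures
establish the estimators' correctness and calibration, not ecological
realism.

## Numerical choices and conventions

* Permutation p-values use (1 + b)/(1 + n_perm) everywhere, so p ≥
  1/(1 + n_perm) and exact-test ties count toward b (conservative);
  exhaustive K_ST enumeration reports the exact arrangement fraction
  instead.
* Statistic comparisons in permutation counts use a 10⁻¹² tolerance so
  floating-point ties count as ties.
* Missing genotypes always blank a whole locus, never one allele;
  half-called inputs are rejected at parse time.
* GenePop files are re-emitted in normalized 3-digit comma dialect, so
  write∘read is byte-stable after one normalization pass.
* Alignment trimming windows are 1-based inclusive throughout.
* Timestamps are normalized to UTC; naive inputs are taken as UTC, and
  no timezone is inferred from coordinates.
* Result tables carry a `# sealpop <version> seed=<seed>` comment line.

## Test and acceptance problem sizes

Calibration suites use 200 null replicates per test family with 99–199
permutations each, sized so the whole suite runs in well under a minute
while keeping the 95% binomial interval around α = 0.05 informative
(±0.03). Parameter-recovery checks use 2 sites × 50 individuals × 9
loci × 20 replicates; topology recovery uses 3 sites × 30 individuals
over 10 seeds; the structure-pattern checks use the 11-site survey at
20 individuals per site over 5 seeds with a majority-of-seeds
criterion, reflecting that single-fixture F_ST values fluctuate a few
hundredths around their drift targets.

## Known limitations

* The HWE Monte-Carlo test is slightly conservative for few-allele loci
  at small n because of probability ties; the suite verifies it against
  full enumeration at tiny n.
* θ and Φ_ST are moment estimators; no confidence intervals are
  provided (bootstrap over loci is out of scope).
* The pipeline's AMOVA and K_ST screens treat markers independently;
  there is no combined-marker test, mirroring the three-screen survey
  design.
* `speed_filter` is greedy, not globally optimal; pathological tracks
  could admit a smaller removal set.
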