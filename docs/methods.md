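# Methods

## The problem

When a genome contains a segmental duplication (SD) that is missing from the
reference assembly, short reads from both copies align to the single
reference locus.  Such *collapsed duplications* merge paralogous variation
into apparent allelic variation: a fixed difference between the two copies —
a paralogous sequence variant (PSV) — is called as a heterozygous SNV in
every duplication carrier.  Two consequences follow.  First, classical
neutrality statistics computed over duplicated or collapsed regions no
longer behave as their single-copy theory assumes, because interlocus gene
conversion (IGC) drives concerted evolution of the copies.  Second,
population diversity estimates inside copy-number-variable (CNV) regions are
inflated for carriers, and the inflation carries a tell-tale signature: the
offending SNVs violate Hardy–Weinberg equilibrium (HWE).

`dupdiv` implements both halves of that argument as testable code: a
mechanistic forward simulator that produces the expected distributions of
the statistics over duplicated and collapsed samples, and an audit pipeline
that measures the diversity inflation and its HWE signature in cohort-style
SNV + CNV call sets.

## Duplication simulator (`dupsim`)

Wright–Fisher, N diploids (2N chromosomes), discrete generations, no
selection.  Every chromosome carries three homologous blocks of B bp: a
single-copy control and an original/duplicated pair; the duplication is
fixed from generation 0 (the model addresses post-fixation equilibrium
only; pre-fixation copy-number dynamics are out of scope).  Infinite-sites
mutation with real-valued positions on [0, B) — collision probability zero,
so no back-mutation bookkeeping.

Per chromosome per generation, with all rates given in coalescent 4N-scaled
units so they are directly comparable across population sizes:

| parameter | meaning | default | per-generation rate |
|---|---|---|---|
| `theta_site` | scaled mutation rate per site | 0.001 | `theta_site*B/(4N)` new mutations per block (Poisson) |
| `R` | scaled crossover rate | 10 | crossover probability `R/(4N)` per gamete |
| `C` | scaled IGC rate | 1 | conversion initiation probability `C/(4N)` |
| `igc_tract_mean` | mean conversion tract (bp) | 100 | geometric tract length, truncated at block edges |

Crossover is limited to the single-copy block (one uniform breakpoint; the
duplication pair is inherited intact from the first parent chromosome).
IGC copies the donor's mutation content inside a uniform-start geometric
tract into the acceptor, direction original→duplicated or the reverse with
probability 1/2, with no sequence-similarity requirement.  With these
scalings the neutral expectation E[π per site] = `theta_site` holds for the
single-copy block, which the test-suite verifies by Monte Carlo.

Full-scale defaults are N=1000, B=5000 bp, t=100 000 generations, z=50
sampled chromosomes, with IGC rates {0.5, 1, 5} and crossover rates
{1, 10, 100} spanning the grid of interest.  The tract-length mean (100 bp)
and `theta_site` (0.001) are documented assumptions; they shift the scale
of the statistics, not the direction of any contrast reported here.

Sampling modes: `single_copy`, `original` and `duplicated` return one
block for z chromosomes drawn without replacement, restricted to sites
segregating in the sample with derived (0/1) coding.  `collapsed`
mimics collapsed mapping: z distinct chromosomes are drawn and the first
z/2 contribute their original block, the rest their duplicated block (the
alternative — z/2 chromosomes contributing both copies — is available with
`paired=True`; the two differ only in within-individual sampling
correlation).  A fixed inter-copy difference therefore surfaces at sample
frequency 1/2, which is what drives Tajima's D positive in collapsed
samples at low IGC.

Implementation: the population is held as boolean chromosome × site
matrices (one for the single-copy block, a position-aligned pair for the
duplicates so a conversion tract is a column slice).  The per-chromosome
set semantics (`ChromosomeState`, `igc_transfer`, `crossover_gamete`) are
exposed separately and serve as oracles for the matrix engine in the
equivalence tests.  Sites fixed or lost population-wide are pruned each
generation — for the duplication pair only sites jointly fixed or jointly
absent in *both* copies, since a site fixed in one copy is still a
divergence (and collapsed-polymorphism) signal.

## Selection comparator (`selsim`)

A minimal forward diploid Wright–Fisher simulator of a single-copy block
with one selected site at the midpoint, used to place the duplication
statistics next to sweep and balancing scenarios.  Genotype fitnesses are
(1, 1+SaA/2N, 1+SAA/2N) with the conventional scaled coefficients:
complete sweep (SAA=40, SaA=0), incomplete sweep (SAA=40, SaA=20),
balancing selection (SAA=0, SaA=40), neutral (0, 0).  The beneficial
allele is introduced as a single copy after a neutral burn-in; runs that
lose it restart from the equilibrium snapshot (rejection-style
conditioning, which — as with any conditioned trajectory method — samples
successful trajectories only).  Sampling rules: complete sweep at
fixation; incomplete sweep when the population frequency first reaches
0.8 (the sampled sweep stage is not dictated by the scenario definitions,
so it is a configurable parameter); balancing after a further 10N
generations of maintained polymorphism.  The selected site is included in
the output matrix when it segregates in the sample.

This comparator is a deliberately simple forward model, not a re-creation
of coalescent selection machinery; it is used for directional contrasts
(e.g. incomplete sweeps push Fay & Wu's H negative) at matched θ, R and
locus length.

## Summary statistics (`sumstats`)

* π: Σ_sites 2k(n−k)/(n(n−1)), the mean pairwise Hamming distance;
  per-site values divide by the block length.
* Watterson's θ_W = S/a1, a1 = Σ_{i<n} 1/i.
* Tajima's D with the standard 1989 constants; NaN when S=0 (replicate
  means use NaN-aware averaging rather than folding undefined values to 0).
* Fay & Wu's H = θ_π − θ_H, θ_H = Σ 2ξ_i i²/(n(n−1)) — the original
  unnormalized form; requires derived coding.
* Nei's haplotype diversity dh = n/(n−1)(1 − Σ p_h²) over distinct row
  strings.
* Genotype-level π: per SNV with m non-missing diploids and alternate
  frequency p̂, the unbiased contribution 2m/(2m−1)·2p̂(1−p̂); identical to
  haplotype π over the 2m alleles, hence phasing-free.  Missing genotypes
  reduce m per site; they are never imputed.
* HWE exact test: two-sided conditional test on heterozygote counts given
  allele counts (probability-mass ordering), computed by the stable
  mid-out recurrence.  Verified against full enumeration in the tests.

## CNV diversity audit (`cnvdiv`)

Inputs: biallelic SNV genotypes (VCF), per-sample CN allele pairs per CNV
region (TSV or symbolic-allele VCF), optional population assignments.
Steps and the rules they follow:

1. **CN status.**  CN− = carries a deletion and no duplication (CN0/CN0 or
   CN0/CN1); CNr = CN1/CN1; CN+ = any allele ≥ CN2.  CN− samples are
   classified but excluded from all comparisons.
2. **Eligibility.**  ≥ 20 CNr and ≥ 20 CN+ samples in the population;
   one random draw of 20 + 20 per CNV per run (no resampling average), the
   seed recorded in the report.
3. **Flanks.**  Same length as the CNV, 1 kb away from each boundary;
   flank SNVs overlapping any other CNV are masked; a 5′ flank running
   below coordinate 0 makes the CNV unusable (logged).
4. **π.**  Per-site genotype π per region (5′ flank / CNV / 3′ flank) and
   group.  CNVs with < 2 SNVs segregating among the 40 drawn samples in
   any region are excluded (the rule's denominator is not dictated by the
   procedure definition; the union of the drawn groups is used here).
5. **Paired tests.**  Per region type, two-sided paired t over per-CNV
   (CN+ − CNr) values, pooled and per population.  Percent increase is
   100·mean(Δ)/mean(CNr) (ratio of means; per-CNV percent averaging is a
   flag away in `paired_comparison` consumers).
6. **HWE.**  Per group, the fraction of the group's polymorphic in-CNV
   SNVs with exact-test p < 0.05 (group-monomorphic SNVs are excluded from
   the denominator).  Fractions are compared with the same paired t —
   the comparison test is not dictated by the procedure, so the π
   comparison's test is mirrored — for all CNVs and again excluding CNVs
   whose CNr fraction is zero.
7. **HWE-filtered π.**  π inside the CNV recomputed per group using only
   SNVs with p ≥ 0.05 *within that group*.  Per-group filtering is the
   choice consistent with the mechanism under test: obligate-heterozygote
   PSVs fail HWE in the CN+ group only, so filtering removes them from
   CN+ while leaving CNr untouched.

Every eligible CNV ends up either in the results or in the exclusion log
with its reason; the report writes tidy TSVs, a flank BED for audit, and a
human-readable summary.

## Synthetic cohorts (`synthgen`)

The generator emulates the statistical structure the audit assumes, so the
pipeline is fully testable offline:

* CN genotypes: per-chromosome alleles CN2 with probability `dup_freq`,
  else CN1 (CN0 available via `deletion_freq`, default off since the audit
  uses CNr/CN+ only).
* Background SNVs: per region, Poisson-many with mean `theta_site·L·a1(2n)`
  (the neutral expected segregating-site count), derived counts from the
  neutral spectrum P(i) ∝ 1/i, genotypes binomial — i.e. HWE, no linkage.
* PSVs: `psv_count` positions inside each CNV, heterozygous in every CN+
  sample and homozygous reference otherwise — the collapsed fixed
  inter-copy difference.
* `spike_igc_like_variants`: optional confounder channel; in-HWE,
  intermediate-frequency variants segregating among carriers only, which
  raise carrier π *without* breaking HWE and therefore survive HWE
  filtering — the signature that distinguishes historical IGC from
  collapse artifacts.

Defaults are chosen once as the study conditions: 100 samples (cohort-scale
population panels), 60 CNVs of 5000 bp, `dup_freq` = 0.3 (expected ≈ 49
CNr / 51 CN+ per 100 samples, comfortably above the 20 + 20 eligibility
bar), `theta_site` = 0.001 (human-scale heterozygosity), `psv_count` = 2
(closed-form Δπ = 2·(40/39)·0.5/5000 ≈ 2.05×10⁻⁴, a realistic
per-site magnitude for cohort-scale data given θ ≈ 10⁻³).  The truth channel records PSV positions,
carrier ids and the closed-form expected per-site Δπ
`k·(2m/(2m−1))·0.5/L`, against which recovery is tested.

What the generator does *not* model: linkage disequilibrium and haplotype
structure among background SNVs, genotyping error, CN genotype error, and
mosaic/partial CNV overlap with SNV calls.  Passing recovery tests
therefore demonstrate correctness of the pipeline's arithmetic and logic
under its own assumptions, not robustness to real-data pathologies.

## Numerical and design choices

* One `numpy` Generator per run seeds every stochastic draw; replicate
  batches spawn independent child streams from a root `SeedSequence`, so
  all outputs are reproducible bit-for-bit given a seed.
* Statistics return NaN (not 0) where undefined (S=0; zero-variance paired
  deltas); aggregations are NaN-aware.
* Genomic intervals are 0-based half-open internally; VCF positions are
  converted at the I/O boundary.
* ms-format positions are written with 8 decimals; round-tripping is exact
  to that precision.
* Test-scale simulations use N=100, B=1000, z=50, 200 replicates and
  t=5000 = 25·2N generations — the same t/2N ratio as the full-scale
  defaults, chosen as the smallest scale at which the directional
  contrasts are comfortably resolved by Monte Carlo.
* The incomplete-sweep sampling frequency (0.8) and the balancing holding
  time (10N) are configurable scenario parameters.

## Known limitations

* The duplication simulator models exactly two copies, no
  similarity-dependent IGC, no NAHR, and no pre-fixation phase.
* The selection comparator conditions by restart, which (intentionally)
  biases toward successful trajectories; absolute sojourn-time statistics
  should not be read off it.
* The audit's paired t on per-CNV HWE-failure fractions treats fractions
  as approximately normal deltas; with few SNVs per CNV the fractions are
  coarse, which the per-CNV SNV counts in the report make visible.
* Real cohort analyses involve release-specific call-set quirks (overlap
  conventions, multi-allelic CNV records, mixed SV classes) that the TSV
  schema used here deliberately abstracts away.
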