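# dupdiv

Diversity estimation in duplicated and copy-number-variable regions.

When a segmental duplication is missing from the reference assembly, short
reads from both copies pile onto one locus.  These *collapsed duplications*
turn fixed differences between the copies (paralogous sequence variants,
PSVs) into apparent heterozygous SNVs in every duplication carrier —
inflating diversity estimates and leaving a Hardy–Weinberg disequilibrium
fingerprint.  Independently, interlocus gene conversion (IGC) between real
duplicate copies distorts the site-frequency spectrum so that classical
selection scans misread duplications as selective signatures.

`dupdiv` is for population geneticists who want to quantify both effects:

* **`dupdiv.dupsim`** — forward-time Wright–Fisher simulator of a fixed
  two-copy duplication plus a single-copy control block under IGC
  (population-scaled rate *C*), crossover (*R*, single-copy block only) and
  infinite-sites mutation (*θ* per site).  Samples are emitted per block or
  as a *collapsed* sample (half the sequences from each copy), in Hudson
  ms format.
* **`dupdiv.selsim`** — matched forward simulator of a single-copy region
  with one selected site (complete sweep `SAA=40, SaA=0`, incomplete sweep
  `SAA=40, SaA=20`, balancing `SAA=0, SaA=40`, neutral), for side-by-side
  comparison of duplication artifacts with true selective signatures.
* **`dupdiv.sumstats`** — π, S, Watterson's θ, Tajima's *D*, Fay & Wu's *H*
  (unnormalized), Nei's haplotype diversity *dh*, genotype-level π from
  unphased VCF genotypes, and the exact Hardy–Weinberg test.
* **`dupdiv.cnvdiv`** — the cohort audit: classify samples per CNV as
  CN−/CNr/CN+, draw 20 + 20 CNr/CN+ groups, compare per-site π inside each
  CNV against same-size flanks 1 kb away, compute per-group HWE-failure
  fractions, and recompute π after HWE filtering — with paired *t* tests
  pooled and per population.
* **`dupdiv.synthgen`** — synthetic cohort generator (SNV VCF + CNV table +
  truth JSON) planting background HWE SNVs, obligate-heterozygote PSVs and
  optional IGC-like in-HWE carrier variants, so the whole audit runs and is
  tested offline.

## Worked example

Simulate 200 replicates of a duplication under low IGC, compute statistics,
and audit a synthetic cohort:

```python
import numpy as np
from dupdiv.dupsim import SimConfig, simulate_batch
from dupdiv import sumstats as ss
from dupdiv.synthgen import SynthConfig, generate_cohort
from dupdiv.cnvdiv import run_pipeline

cfg = SimConfig(N=100, B=1000, t=5000, z=50, C=0.5, R=10, theta_site=1e-3)
batch = simulate_batch(cfg, 200, seed=1)
pi_sc  = np.mean([ss.nucleotide_diversity(r["single_copy"], per_site=True) for r in batch])
pi_dup = np.mean([ss.nucleotide_diversity(r["duplicated"],  per_site=True) for r in batch])
d_col  = np.nanmean([ss.tajimas_d(r["collapsed"]) for r in batch])
print(f"pi single-copy {pi_sc:.2e}  pi duplicated {pi_dup:.2e}  D collapsed {d_col:+.2f}")

coh = generate_cohort(SynthConfig(seed=5))        # 100 samples, 60 CNVs, 2 PSVs each
report = run_pipeline(coh.genotypes, coh.cnv_table, seed=7)
print(report.summary())
```

This prints (values vary slightly with seed):

```
pi single-copy 9.75e-04  pi duplicated 1.39e-03  D collapsed +2.75
cnvdiv pipeline report (seed=7)
analyzed 60 CNV x population combinations; 0 excluded
  pi   pooled flank5: mean d(pi) = -3.641e-06 (-0.4%), paired t p = 0.748 (n=60)
  pi   pooled    cnv: mean d(pi) = +2.088e-04 (+21.1%), paired t p = 3.21e-28 (n=60)
  pi   pooled flank3: mean d(pi) = -5.265e-06 (-0.5%), paired t p = 0.604 (n=60)
  HWE-failure fraction   pooled [all]: d = +0.092, p = 1.17e-22 (n=60)
  HWE-failure fraction   pooled [cnr_fraction_nonzero]: d = +0.045, p = 4.12e-06 (n=17)
  HWE-filtered pi   pooled cnv: d(pi) = +3.701e-06, p = 0.779 (n=60)
```

Read: the single-copy block is calibrated at its neutral expectation
(π ≈ θ = 10⁻³) while the duplicated copy is ~40% more diverse; collapsed
samples show positive Tajima's *D*.  In the cohort, duplication carriers
(CN+) are significantly more diverse than CNr samples *inside* CNVs but
not in the flanks, the carriers have an excess of HWE failures, and the
π contrast disappears once HWE-failing SNVs are filtered — the planted
collapsed-duplication signature, fully recovered.

The same workflows are scriptable from the shell.  Without `--config` the
simulator runs its full-scale defaults (N=1000, t=100 000 generations —
minutes per replicate); pass a config for quick runs:

```bash
cat > scratch/sim.yaml <<EOF
N: 100
B: 1000
t: 5000
z: 50
C: 0.5
R: 10
EOF
dupdiv sim --config scratch/sim.yaml --reps 10 --seed 1 --out scratch/igc
dupdiv stats --in scratch/igc.dup.ms --block-length 1000 --out scratch/stats.tsv
dupdiv cohort --seed 5 --out scratch/cohort
dupdiv audit --vcf scratch/cohort/cohort.vcf --cnv scratch/cohort/cnvs.tsv \
             --seed 7 --out scratch/report
dupdiv inspect scratch/cohort/cohort.vcf
```

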