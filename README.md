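# clinekit

Spatial population genomics of genome-wide SNP data at micro-geographic
scale: quality control, pairwise relationship matrices, ordination,
Weir–Cockerham Fst, spatial autocorrelation, cline-orientation inference,
per-SNP gradient scanning, and a spatially explicit two-wave
range-expansion simulator.

## The problem

Within a single country, allele-frequency differences between sampling
sites are tiny (pairwise Fst of order 10⁻³–10⁻⁴), yet systematic sampling
can still reveal a *cline* — a gradual geographic gradient in genomic
diversity. Two questions follow. First, detection: is genomic covariance
spatially autocorrelated, and at what compass bearing is the gradient
steepest? Second, interpretation: does such a cline require ancient
demographic events (serial founder effects of prehistoric expansions), or
can a recent regional discontinuity — a coastal strip depopulated for a few
dozen generations and then recolonized by neighbours — produce an
indistinguishable gradient? `clinekit` implements the full analysis chain
for the first question and the lattice simulator for the second, together
with a synthetic-data generator with known planted structure so every stage
is testable offline. It is written for population geneticists working with
site-referenced genotype cohorts (VCF or PLINK text).

## Core statistics

* **Weir–Cockerham Fst** — per-SNP variance components a, b, c with
  θ̂ = a/(a+b+c), combined across SNPs as Σa/Σ(a+b+c), pairwise between
  subpopulations above a size floor, negatives clamped in the matrix only.
* **Spatial autocorrelogram** — genetic covariance c_ij (double-centred
  mean squared dosage distance) summed within 24 geodesic distance classes,
  r_h = Σ_{pairs∈h} c_ij / Σ_{incident i} c_ii, permutation significance by
  shuffling individuals between subpopulations, and an ensemble-ranked
  Fisher combined P.
* **Bearing correlogram** — the Mantel correlation r(θ) between a genetic
  distance matrix and d_ij·cos²(α_ij − θ) on a 1° grid; the argmax over
  [0, 180) is the cline orientation, in degrees clockwise from north.
* **Classical MDS with Cailliez correction, symmetric Procrustes/protest,
  GMM clustering (BIC), AMOVA, exact HWE, Kendall τ-B LD pruning, local
  Moran's I genome scan** — see `docs/methods.md` for every formula and
  convention.

## Worked example

```python
import numpy as np
from clinekit.synth import SynthConfig, dutch_site_fixture, generate_clinal_dataset
from clinekit.differentiation import wc_fst
from clinekit.spatial import bearing_correlogram

sites = dutch_site_fixture()          # 54 sites with published coordinates
cfg = SynthConfig(n_snps=2000, n_individuals=10,
                  cline_bearing=110.0, cline_strength=0.2, seed=0)
gm, st, truth = generate_clinal_dataset(cfg, sites)

fst = wc_fst(gm, st, min_n=10)        # pairwise combined Fst, 54 sites
off = fst.pairwise.values[np.triu_indices(fst.pairwise.n, 1)]
print(f"mean pairwise Fst: {off.mean():.4f}")

prof = bearing_correlogram(fst.pairwise, st, n_perm=999, seed=1)
print(f"cline bearing: {prof.argmax:.0f} deg, "
      f"r = {prof.r_at(prof.argmax):.3f}, p = {prof.p[int(prof.argmax)]:.3f}")
```

Output:

```
mean pairwise Fst: 0.0050
cline bearing: 106 deg, r = 0.863, p = 0.001
```

The generator planted a 110° (southeast–northwest) frequency cline; the
bearing correlogram recovers it within a few degrees, the Mantel
correlation at the maximum is strong, and the permutation p is at the floor
1/(B+1) — the cline is unambiguous despite a mean pairwise Fst below 0.01.

The same analyses run from the shell:

```bash
clinekit synth --out data/ --seed 0
clinekit qc --vcf data/synth.vcf --sites data/sites.tsv \
            --assignment data/assignment.tsv --out qc/
clinekit fst --vcf data/synth.vcf --sites data/sites.tsv \
             --assignment data/assignment.tsv --out fst.tsv
clinekit bearing --fst-matrix fst.tsv --sites data/sites.tsv --out profile.tsv
clinekit simulate --scenario discontinuity --out sim/ --seed 1
clinekit run --config run.yaml --out results/     # full pipeline + manifest
```

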