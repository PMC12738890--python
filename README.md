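# tiliapop

Population-genetic analysis and demographic inference for codominant
microsatellite (SSR) surveys of structured tree populations, built around a
two-species *Tilia* design: 11 populations (8 *T. amurensis*, 3
*T. japonica*, N = 242) genotyped at 15 dinucleotide loci.

The package covers the full analysis such a survey needs:

* **Diversity** — per-population Na, Ne = 1/Σp², Shannon's I = −Σp ln p,
  observed and expected heterozygosity (He = 1 − Σp²), and the inbreeding
  coefficient F<sub>IS</sub> = (He − Ho)/He, each with standard errors
  across loci.
* **Differentiation and gene flow** — pairwise and global
  F<sub>ST</sub> = (H<sub>T</sub> − H<sub>S</sub>)/H<sub>T</sub>
  (Weir–Cockerham θ available), and the island-model migrant number
  N<sub>m</sub> = (1/F<sub>ST</sub> − 1)/4.
* **AMOVA** — among/within-population partition of Smouse–Peakall squared
  codominant distances with permutation P-values.
* **Ordination and clustering** — Nei (1978) unbiased genetic distance,
  principal coordinate analysis, UPGMA dendrograms (Newick), and Evanno's
  ΔK = |L″(K)| / sd(L(K)) over replicate Bayesian-clustering
  log-likelihoods.
* **Demographic inference (ABC)** — a coalescent simulator for SSR data
  under a generalized stepwise mutation model (geometric step sizes with
  coefficient P, bounded 40-state allele ladder, single-nucleotide indels)
  and three competing four-group demographic scenarios (nested splits;
  nested splits with an admixed origin of one group; simultaneous
  divergence). Approximate Bayesian computation with rejection sampling,
  scenario choice by multinomial logistic regression on the closest
  simulations, Beaumont-style local-linear parameter adjustment on PLS
  components, and PCA model checking. Event times convert to calendar ages
  as t × generation time / 1000 ka BP (default generation time 100 yr).

Because the original genotypes are not public, a synthetic-data module
generates study-shaped datasets (exact sample sizes, two species-level
clusters, per-population inbreeding) so that every stage is testable.

## Worked example

```python
from tiliapop import (FixtureConfig, make_study_fixture, population_summary,
                      amova, global_fst, nm_from_fst, nei_distance, upgma)
from tiliapop.synthetic_data import STUDY_POPULATIONS

ds = make_study_fixture(FixtureConfig(seed=1))       # N=242, 15 loci
species = {s.label: s.species for s in STUDY_POPULATIONS}

print(population_summary(ds, species).formatted().head(3).to_string())
am = [p for p in ds.population_labels if species[p] == "T. amurensis"]
print(amova(ds, n_permutations=999, seed=0, populations=am)
      .to_dataframe().round(3).to_string())
fst = global_fst(ds, am)
print(f"T. amurensis FST = {fst:.3f}, Nm = {nm_from_fst(fst):.3f}")
```

prints

```
                Na             Ne              I             Ho             He            Fis
TS   4.867 ± 0.322  3.213 ± 0.296  1.241 ± 0.086  0.651 ± 0.050  0.649 ± 0.032  0.013 ± 0.047
LU   4.933 ± 0.284  3.177 ± 0.239  1.266 ± 0.073  0.608 ± 0.042  0.658 ± 0.027  0.088 ± 0.047
YDS  4.733 ± 0.284  3.171 ± 0.238  1.249 ± 0.073  0.624 ± 0.038  0.655 ± 0.030  0.034 ± 0.050

                     df        SS  variance  pct_of_variation      P
Among populations     7   163.062     0.544                 5  0.001
Within populations  176  1911.710    10.862                95  0.001
Total               183  2074.772    11.406               100    NaN

T. amurensis FST = 0.044, Nm = 5.412
```

The diversity table mirrors the usual "value ± SE" layout; the AMOVA rows
give degrees of freedom (7 among / 176 within / 183 total for the 8
*T. amurensis* populations), sums of squares, method-of-moments variance
components, integer percentages of variation, and the permutation
P-value. Here 5% of the molecular variance lies among populations of this
synthetic dataset, and the global F<sub>ST</sub> of 0.044 corresponds to
about 5.4 effective migrants per generation under the island model.

A command-line interface wraps each stage
(`tiliapop stats|amova|pcoa|upgma|deltak|simulate|abc|all`); `tiliapop all
--seed 7 --out report/` writes the complete report directory (CSV tables,
Newick tree, ABC JSON, run manifest) from a single master seed.

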