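# coliaspop

Population-genomic tests for the origin and maintenance of **Alba**, the
female-limited white/coloured wing polymorphism of *Colias* butterflies.
Alba is inherited as a single dominant autosomal allele; the question the
package addresses is whether such a polymorphism, shared across a species
radiation, has one origin and how it persists — by repeated introgression
between species, by balancing selection within them, or both.

`coliaspop` provides, as a tested and reusable library plus CLI:

* **ABBA-BABA introgression statistics over species trios** — Patterson's
  D from frequency-weighted site-pattern sums, with
  `ABBA = (1−p₁)p₂p₃(1−p₄)` and `BABA = p₁(1−p₂)p₃(1−p₄)` per site,
  `D = Σ(ABBA−BABA)/Σ(ABBA+BABA)`; a weighted delete-one block jackknife
  for Z and p; the conservative minimal-D (`Dmin`) summary over the three
  arrangements of each trio; and Holm step-down multiple-testing
  correction across trios.
* **f4-ratio and f-branch** — the admixture-fraction estimator
  `f̂ = S(P1,P2;P3,O)/S(P1,P3;P3,O)` and its decomposition onto species-tree
  branches, `f_b(C) = median_a min_A f(A, a; C, O)`, attributing excess
  derived-allele sharing to ancestral versus terminal branches.
* **Windowed scans** — `d_f` (distance fraction) and `f_dM` in
  non-overlapping 500-SNP windows, plus a morph-grouped locus outlier
  enrichment test (Pearson chi-squared on outlier counts by the wing
  colour of the P2/P3 species).
* **Divergence and relative node depth** — windowed
  `d_XY` with an all-sites callable denominator, `RND = d_XY /
  [(d_XO + d_YO)/2]` against a shared outgroup, lower-tail outlier calls
  (introgressed tracts have recent coalescence, hence low RND), windowed
  nucleotide diversity and Tajima's D.
* **Coverage × phenotype segregation scan** — binary read-coverage
  presence per species per 600-bp window, the per-window Alba/coloured
  mean presence difference `bias = A_mean − O_mean`, and the search for
  windows where coverage segregates perfectly with wing colour.
* **Balancing-selection test** — the folded allele-frequency spectrum of
  high-confidence intergenic indels versus the Alba allele frequency
  obtained from field phenotype counts via the Hardy–Weinberg dominant
  conversion `q = 1 − √(1−f)`.
* **Synthetic-data generators** — a per-site coalescent for species
  quartets/quintets with an admixture pulse of fraction γ, an
  introgressed-tract scenario for RND, a coverage matrix with one planted
  morph-segregating window, and an indel table with a neutral folded
  spectrum plus one planted balanced variant — each returning its ground
  truth, so every stage of the pipeline is testable without downloads.

## Worked example

Simulate a species quartet (((P1,P2),P3),O) in which 30% of the genome of
P2 traces to P3 through a recent admixture pulse, then estimate
introgression:

```python
from coliaspop.simulate import QuartetSimParams, simulate_quartet
from coliaspop import introgression as ig, balancing as bal

params = QuartetSimParams(gamma=0.3, n_sites=200_000, seed=42)
gm, truth = simulate_quartet(params)
pops = truth.pop_samples
sums = ig.site_pattern_sums(gm, pops["P1"], pops["P2"], pops["P3"], pops["O"])
d = ig.patterson_d(sums)
z, p = ig.jackknife_significance(sums)
f = ig.f4_ratio(gm, pops["P1"], pops["P2"], pops["P3"], pops["O"])
print(f"{gm.n_sites} SNPs retained")
print(f"D = {d:.3f}, Z = {z:.1f}, p = {p:.2e}")
print(f"f4-ratio admixture fraction = {f:.3f} (simulated gamma = {params.gamma})")
q = bal.hw_dominant_allele_freq(0.72)
print(f"Alba allele frequency at 72% phenotype frequency: q = {q:.3f}")
```

prints

```
29917 SNPs retained
D = 0.737, Z = 51.7, p = 0.00e+00
f4-ratio admixture fraction = 0.290 (simulated gamma = 0.3)
Alba allele frequency at 72% phenotype frequency: q = 0.471
```

The D statistic is strongly positive (excess ABBA sharing between P2 and
P3), the block-jackknife Z leaves no doubt about significance, and the
f4-ratio recovers the simulated admixture fraction. The last line is the
Hardy–Weinberg dominant conversion: where 72% of females show the dominant
Alba phenotype, the Alba allele segregates at frequency ≈ 0.47 — far above
the 95th percentile of typical genome-wide indel frequency spectra, the
signature of balancing selection.

The same analyses are available as CLI subcommands
(`coliaspop simulate | dtrios | dinvestigate | fbranch | rnd | popstats |
covscan | balancing | demo`); `coliaspop demo --seed 1 --outdir out/`
chains every stage over synthetic inputs and writes a report asserting
that each planted truth was recovered.

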