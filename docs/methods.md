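# Methods

This note documents the statistical procedures implemented in
`coliaspop`, the modelling assumptions behind them, the defaults that
matter, and what the synthetic-data generators do and do not emulate.

## Genotypes, polarisation and missing data

All statistics operate on biallelic SNP genotypes stored as diploid
alt-allele dosages (0/1/2, missing preserved). Multi-allelic and indel
records are skipped on VCF read (SVs come through a dedicated SV-VCF
reader). Internally all coordinates are 0-based half-open; VCF positions
are shifted by exactly one on read/write.

Population allele frequencies at a site use only non-missing genotypes.
For pattern statistics a site is *usable* when all four populations have
at least one non-missing call and the outgroup has a major allele; the
derived allele is defined as the non-outgroup-major allele, and sites with
an exact 50/50 outgroup tie are dropped (ancestral state unresolvable).
This is the standard frequency-based ABBA-BABA treatment; it uses
polymorphic outgroup sites rather than discarding them.

## Patterson's D, blocks, and the weighted jackknife

Per usable site, `ABBA = (1−p₁)p₂p₃(1−p₄)` and `BABA = p₁(1−p₂)p₃(1−p₄)`;
`D = Σ(ABBA−BABA)/Σ(ABBA+BABA)`. Sites are partitioned into contiguous
equal-SNP blocks (default 20, configurable) and significance comes from a
delete-one block jackknife weighted by each block's `ABBA+BABA` mass
(Busing-style delete-m variance), `Z = D/SE` with a two-sided normal
tail. Windows/blocks whose denominator vanishes are flagged undefined,
never reported as zero. With g = 20 blocks the finite-block reference for
|Z| is slightly heavier-tailed than normal (≈ t₁₉); the calibration tests
account for this. A degenerate SE of zero (all delete-one estimates
identical) yields a flagged, undefined p.

For each trio all three arrangements (choices of P3) are evaluated, each
oriented so D ≥ 0 by swapping P1/P2; the reported `Dmin` is the smallest
oriented D — a conservative estimate agnostic to the true topology — and
its arrangement supplies the Z and raw p. Holm's step-down correction is
applied across all trios of a run. For species polymorphic for the wing
morph, the caller can restrict to Alba-morph samples
(`alba_only_species`), keeping the morph grouping of trios well defined.

## f4-ratio and f-branch

The admixture fraction is estimated as
`f̂ = Σ(ABBA−BABA)[P1,P2;P3,O] / Σ(ABBA−BABA)[P1,P3ₐ;P3ᵦ,O]`, where the
denominator substitutes the donor for P2. With a single donor population
the two donor slots use the unbiased sampling-without-replacement
estimators `p̂3² → c(c−1)/(n(n−1))` and `p̂3(1−p̂3) → c(n−c)/(n(n−1))`
(c derived-allele count of n chromosomes), which avoids the upward bias
of squaring a small-sample frequency. Under a pulse of fraction γ at time
t_gf into P2, the estimator's expectation is γ(1 − t_gf/t₁₂₃); with the
generator defaults this attenuation is below the reporting tolerance.

The f-branch statistic attributes excess sharing to branches:
for branch b with sister clade S and candidate donor C (C not below b),

    f_b(C) = median over recipients a ∈ descendants(b)
             of min over proxies A ∈ S \ {C}
             of f̂(A, a; C, O).

The inner minimum makes the attribution conservative (any proxy lineage
without the excess suppresses the cell), the outer median makes it robust
across recipients. Terminal branches appear as rows alongside internal
branches; cells that are topologically inadmissible (no proxy available,
or C below b) are undefined. Negative cells are clamped to zero in the
matrix display; raw values are retained in the TSV output.

## Windowed scans: f_dM and the distance fraction d_f

Scans run in non-overlapping windows of exactly 500 usable SNPs (default;
trailing partial windows are dropped), per chromosome.

`f_dM` shares the `Σ(ABBA−BABA)` numerator and uses the dynamic-donor
denominator: per site, if p₂ ≥ p₁ the larger of (p₂, p₃) replaces both
donor slots; otherwise the larger of (p₁, p₃) does, with a sign flip.
This bounds the statistic to [−1, 1], symmetric about 0 under the null,
positive for P2–P3 sharing and negative for P1–P3 sharing.

`d_f`, the distance fraction, is implemented as

    d_f = Σ(ABBA−BABA) / [ Σ(ABBA−BABA) + 2·Σ d_xy(P2,P3) ]

with `d_xy(P2,P3) = p₂(1−p₃) + p₃(1−p₂)` summed over the window's sites:
the share of the P2–P3 divergence attributable to introgression. It is
bounded above by 1, has expectation 0 under symmetric divergence, and is
positive under P2–P3 gene flow; because the normalisation is absolute
divergence rather than a pattern count, the statistic stays informative
for old introgression events. Windows with a non-positive denominator are
flagged undefined.

The locus enrichment test marks a trio as a locus outlier when any
window overlapping the locus interval exceeds the 95th percentile of that
trio's defined windows on the locus chromosome ("any" aggregation is the
default because a locus can span several windows of which only some carry
the introgressed haplotype; "all" is available as a flag). Outlier counts
are cross-tabulated by the morph group of the (P2, P3) pair
(Alba–Alba / Alba–coloured / coloured–coloured; trios with unknown morphs
are excluded, empty groups dropped with a df adjustment) and tested with
Pearson's chi-squared; for 3 groups × 2 outcomes df = 2 and the upper
tail is exactly `exp(−χ²/2)`.

## Divergence, RND, Tajima's D

`d_XY` is the mean pairwise difference per callable site between two
populations, computed comparison-wise: per variant site
`[c_X(n_Y−c_Y) + c_Y(n_X−c_X)]/(n_X n_Y)` over non-missing chromosomes,
summed and divided by the window's callable-site count (the all-sites
denominator; invariant callable sites contribute zero difference).
Windows without callable information are undefined.

`RND = d_XY / [(d_XO + d_YO)/2]` on windows aligned across the three
series; windows where the outgroup denominator is zero (the "infinite"
values) are removed *before* any quantile computation. Outliers are
values at or below the empirical lower quantile (default 5%), computed
with linear interpolation between order statistics (type-7) — stated
because outlier calls depend on the convention. Default window size is
10 kb (bp mode), configurable.

Windowed Tajima's D uses the canonical constants a₁…e₂ from the number of
chromosomes n and `D = (π − S/a₁)/√(e₁S + e₂S(S−1))`; only fully-called
sites enter a window so n is constant, and S = 0 windows are undefined.
π per callable site is also available comparison-wise.

Percent identity of an alignment with k fixed differences over L bp is
`100(1 − k/L)`, with an integer-percent presentation field.

## Coverage × phenotype scan

Per sample, a window is *covered* when the fraction of its bases at depth
≥ 1 is at least 0.5. These two thresholds are deliberate, exposed knobs:
upstream read filtering (mapping quality, proper pairs) is assumed done at
alignment, and the presence criterion itself is a binarisation choice, so
both are CLI options. Species with several samples are collapsed by
logical OR across their tracks. Per window the scan reports the mean
presence among Alba species (A_mean), among coloured species (O_mean),
their difference (bias ∈ [−1, 1]; unknown-morph species are excluded),
perfectly segregating windows (|bias| ≥ 1 − tol, both signs reported),
and a histogram of biases whose counts conserve the window total.
Default window size 600 bp.

## Balancing-selection test

High-confidence indels are records that are INS/DEL, pass-flagged, fully
genotyped, with every genotype quality ≥ 20 (default), and not
overlapping gene intervals; a dedicated SV-caller germline filter is
tool-internal and is approximated by exactly these stated rules. The
folded AFS takes each record's alt frequency over non-missing diploids
and folds it (`min(f, 1−f)`), so all values lie in [0, 0.5].

Field phenotype counts convert to allele frequencies through the
Hardy–Weinberg dominant map `f = 1 − (1−q)²`, inverted exactly as
`q = 1 − √(1−f)`; the conversion is undefined at f = 1. The published
phenotype range 66–72% gives q = 0.417–0.471 exactly; the package
returns exact values and presents 2 dp, which makes the upper bound 0.47
and the lower 0.42 (a printed lower bound of 0.4 can only reflect
additional rounding or population-specific estimates external to this
pipeline). A population's Alba frequency *exceeds the background* when
q is greater than the empirical 95th percentile of the folded AFS; the
per-population empirical p is the inclusive fraction of indels at folded
frequency ≥ q, with a conservative (count+1)/(n+1) companion column.

## Synthetic-data generators

*Quartet/quintet coalescent.* Sites are independent (no recombination
structure or linkage): per site a genealogy is drawn under a
multi-population coalescent following the species-tree merge schedule,
with an optional admixture pulse — with probability γ the recipient
population's *entire lineage set* moves to the donor at t_gf, i.e. a site
is wholly introgressed or not, matching the locus-level interpretation of
a pulse (an alternative, per-lineage relocation as in general simulators,
has the same f4-ratio expectation but a different D variance; the
cross-check test against msprime therefore compares f4-ratios).
Mutations are Poisson(θ × tree length) collapsed to a single biallelic
mutation placed uniformly by branch length (the infinite-sites
conditional); sites where the outgroup itself is polymorphic are dropped.
Defaults: t_gf = 0.1, t₁₂ = 1, t₁₂₃ = 2, t_root = 3 coalescent units,
θ = 0.01 per site (a heterozygosity level typical of butterfly genomes),
2 diploids per population, 50k sites. The kernel is numba-compiled and
handles ≤ 8 populations / 64 lineages.

*RND scenario.* Sites fall into four mutation categories (X-private,
Y-private, internal X∧Y, outgroup) with rates chosen so E[d_XY] equals
0.02 off-tract and 0.004 on-tract while E[d_XO] = E[d_YO] = 0.05
everywhere — recent introgression shortens only the X–Y coalescence.
Variants are fixed within populations (no within-population polymorphism)
and every base is callable; this isolates the RND signal from estimation
noise in d_XY and is the main idealisation of this generator.

*Coverage.* Non-causal cells are Bernoulli(b = 0.98, roughly the
coverage completeness of conserved single-copy regions); the causal
window equals the morph indicator, flipped with probability ε (default
0). The spurious perfect-bias rate has the closed form
b^k(1−b)^m + (1−b)^k b^m for k Alba and m coloured species, which the
tests verify.

*Indel table.* Neutral records draw a minor count i ∈ {1 … n} with
probability ∝ 1/i + 1/(2n−i) (the folded neutral equilibrium spectrum,
taken literally; the i = n category is not halved) and genotypes
Hardy–Weinberg at i/2n; one planted record carries exactly
round(q*·2n) minor alleles. With 29 diploids the neutral 95th percentile
sits at 26/58 ≈ 0.448, stable across seeds, so a planted 0.47 record
exceeds it essentially always. Real indel spectra are shifted toward rare
variants relative to this equilibrium model (their empirical 95th
percentiles are far lower), so passing this check is a *conservative*
statement about the real-data contrast.

What the generators do **not** emulate: linkage and recombination (block
jackknife behaviour under linkage is exercised with exchangeable blocks,
not linked sites), sequencing/genotyping error, reference bias in read
mapping, population growth or structure within species, and selection.
Passing tests therefore demonstrate correctness of the estimators under
their own model assumptions, not robustness to every property of real
resequencing data.

## Numerical choices and degenerate inputs

* Undefined statistics are `None`/NaN-flagged everywhere, never silently
  zero; undefined windows are removed before any quantile computation.
* Quantiles use linear interpolation (type-7) throughout.
* Equal-SNP blocks/windows drop trailing partial blocks.
* Jackknife requires ≥ 3 blocks with signal; SE = 0 yields undefined p.
* Holm adjustment is the exact step-down maximum, returned in input
  order; single p-values are unchanged.
* The chi-squared test drops empty groups (with a warning) and adjusts
  df; it refuses to run with fewer than 2 non-empty groups.
* Seeds: every generator is deterministic given its seed; orchestrated
  runs derive child seeds from one `SeedSequence`, all below 2³¹.

## Problem sizes

Default scales were chosen so the complete suite runs on a laptop-class
single core in a couple of minutes: null calibration at 500 replicates of
20k sites, admixture-fraction recovery at 200k sites, f-branch
attribution over 100 seeds of 30k sites, 10⁴-window bound checks, a
10⁴-window coverage scan with 21 species, and 100–200 seed replicates of
the indel test at 3k records (one 35k-record run mirrors the real
dataset's size). These are simulation-budget choices; all statistics are
O(sites) and scale linearly.

## Known limitations

* The distance-fraction scan statistic follows the definition given
  above; windows where `Σ(ABBA−BABA) < −2Σd_xy(P2,P3)` (possible only
  under strong P1–P3 sharing in short windows) are undefined rather than
  clamped.
* Direction of gene flow is not inferred (out of scope); Dmin names the
  sharing pair, not the donor.
* The coverage scan assumes the presence calls themselves are reliable;
  repeat-induced multi-mapping must be handled upstream at alignment.
* Tajima's D uses fully-called sites only; heavy, non-random missingness
  will bias S relative to π.
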