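"""ABBA-BABA introgression statistics over species trios.

Implements the genome-wide machinery: frequency-based ABBA/BABA site-pattern
sums with contiguous equal-SNP blocks, Patterson's D with a weighted
delete-one block jackknife, the conservative minimal-D summary over the
three trio arrangements, Holm multiple-testing correction, the f4-ratio
admixture-fraction estimator and its f-branch decomposition over a species
tree, windowed d_f / f_dM scans, and the morph-grouped locus outlier
enrichment test.

Derived-allele polarisation follows standard ABBA-BABA practice: the
derived allele at a site is the allele that is *not* the outgroup-major
allele; sites where the outgroup is exactly 50/50 are dropped.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    GenotypeMatrix,
    Morph,
    MorphGroup,
    SampleSheet,
    WindowMode,
    WindowSpec,
    WindowStat,
)
from .tree import Branch, SpeciesTree

logger = logging.getLogger(__name__)

DEFAULT_JACKKNIFE_BLOCKS = 20
SNPS_PER_WINDOW = 500


# ---------------------------------------------------------------------------
# Site patterns
# ---------------------------------------------------------------------------

@dataclass
class PolarisedFreqs:
    """Derived-allele frequencies for P1..P4 at usable sites."""

    chrom: np.ndarray
    pos: np.ndarray
    p: np.ndarray  # (n_usable, 4) derived-allele frequencies

    @property
    def n_sites(self) -> int:
        return len(self.pos)


def polarised_freqs(
    geno: GenotypeMatrix,
    p1: list[str],
    p2: list[str],
    p3: list[str],
    outgroup: list[str],
) -> PolarisedFreqs:
    """Per-site derived-allele frequencies for a quartet of populations.

    A site is usable when every population has at least one non-missing
    call and the outgroup has a major allele (not a 50/50 tie). The derived
    allele is the non-outgroup-major allele; frequencies are flipped
    accordingly.
    """
    pops = [p1, p2, p3, outgroup]
    for pop in pops:
        if len(pop) == 0:
            raise ValueError("every population needs >= 1 sample")
    freqs = np.column_stack([geno.alt_freqs(pop) for pop in pops])
    usable = ~np.isnan(freqs).any(axis=1)
    usable &= freqs[:, 3] != 0.5  # outgroup allele tie: ancestral state unknown
    f = freqs[usable]
    flip = f[:, 3] > 0.5  # alt is the outgroup-major allele -> derived is ref
    f[flip] = 1.0 - f[flip]
    return PolarisedFreqs(chrom=geno.chrom[usable], pos=geno.pos[usable], p=f)


def _abba_baba(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p1, p2, p3, p4 = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


@dataclass
class SitePatternSums:
    """Blocked ABBA/BABA sums for one trio arrangement."""

    abba: np.ndarray  # per-block sums
    baba: np.ndarray
    block_bounds: np.ndarray  # site-index boundaries, len n_blocks + 1

    def __post_init__(self) -> None:
        if len(self.abba) != len(self.baba) or len(self.abba) < 1:
            raise ValueError("need matching, non-empty block sums")
        if (self.abba < 0).any() or (self.baba < 0).any():
            raise ValueError("pattern sums must be non-negative")

    @property
    def n_blocks(self) -> int:
        return len(self.abba)

    @property
    def total_abba(self) -> float:
        return float(self.abba.sum())

    @property
    def total_baba(self) -> float:
        return float(self.baba.sum())


def site_pattern_sums(
    geno: GenotypeMatrix | PolarisedFreqs,
    p1: list[str] | None = None,
    p2: list[str] | None = None,
    p3: list[str] | None = None,
    outgroup: list[str] | None = None,
    n_blocks: int = DEFAULT_JACKKNIFE_BLOCKS,
) -> SitePatternSums:
    """ABBA/BABA sums partitioned into contiguous equal-SNP blocks."""
    if isinstance(geno, PolarisedFreqs):
        pf = geno
    else:
        pf = polarised_freqs(geno, p1, p2, p3, outgroup)
    if pf.n_sites == 0:
        raise ValueError("no usable sites for pattern sums")
    abba, baba = _abba_baba(pf.p)
    n_blocks = min(n_blocks, pf.n_sites)
    bounds = np.linspace(0, pf.n_sites, n_blocks + 1).astype(np.int64)
    abba_b = np.add.reduceat(abba, bounds[:-1])
    baba_b = np.add.reduceat(baba, bounds[:-1])
    return SitePatternSums(abba=abba_b, baba=baba_b, block_bounds=bounds)


def patterson_d(sums: SitePatternSums) -> float | None:
    """Patterson's D = (ABBA - BABA)/(ABBA + BABA); None if denominator 0."""
    denom = sums.total_abba + sums.total_baba
    if denom == 0:
        return None
    return (sums.total_abba - sums.total_baba) / denom


def jackknife_significance(sums: SitePatternSums) -> tuple[float | None, float | None]:
    """Weighted delete-one block jackknife Z and two-sided normal p.

    Blocks are weighted by their ABBA+BABA denominator (Busing-style
    weighted jackknife). Returns (None, None) when fewer than three blocks
    carry signal or when all delete-one estimates coincide (SE = 0).
    """
    w = sums.abba + sums.baba
    keep = w > 0
    if keep.sum() < 3:
        return None, None
    abba, baba, w = sums.abba[keep], sums.baba[keep], w[keep]
    g = len(w)
    n = w.sum()
    d_full = (abba.sum() - baba.sum()) / n
    num_tot = abba.sum() - baba.sum()
    d_del = (num_tot - (abba - baba)) / (n - w)
    if np.allclose(d_del, d_full):
        return None, None
    h = n / w
    theta_j = g * d_full - ((1.0 - w / n) * d_del).sum()
    tau = h * d_full - (h - 1.0) * d_del
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    se = math.sqrt(var)
    if se == 0:
        return None, None
    z = d_full / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def holm_correct(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# Trio enumeration
# ---------------------------------------------------------------------------

@dataclass
class TrioResult:
    """Minimal-D summary of one species trio."""

    p1: str
    p2: str
    p3: str
    outgroup: str
    d_by_arrangement: dict[tuple[str, str, str], float | None]
    dmin: float | None
    z: float | None
    p_raw: float | None
    p_holm: float | None = None
    morph_group: MorphGroup = MorphGroup.undefined

    @property
    def arrangement(self) -> tuple[str, str, str]:
        return (self.p1, self.p2, self.p3)


def _oriented(sums: SitePatternSums) -> tuple[SitePatternSums, bool]:
    """Swap ABBA/BABA (i.e. P1 and P2) so that D >= 0."""
    d = patterson_d(sums)
    if d is not None and d < 0:
        return SitePatternSums(sums.baba.copy(), sums.abba.copy(), sums.block_bounds), True
    return sums, False


def evaluate_trio(
    geno: GenotypeMatrix,
    species_samples: dict[str, list[str]],
    trio: tuple[str, str, str],
    outgroup: str,
    n_blocks: int = DEFAULT_JACKKNIFE_BLOCKS,
) -> TrioResult:
    """Evaluate the three arrangements of a trio; keep the minimal-D one.

    Each arrangement fixes which species sits in P3; the (P1, P2) order is
    oriented so D >= 0. The reported Z and raw p belong to the minimal-D
    arrangement (the conservative choice of topology).
    """
    a, b, c = trio
    arrangements = [(a, b, c), (a, c, b), (b, c, a)]
    best: tuple[float, tuple[str, str, str], SitePatternSums] | None = None
    d_by_arr: dict[tuple[str, str, str], float | None] = {}
    for s1, s2, s3 in arrangements:
        sums = site_pattern_sums(
            geno,
            species_samples[s1],
            species_samples[s2],
            species_samples[s3],
            species_samples[outgroup],
            n_blocks=n_blocks,
        )
        sums, swapped = _oriented(sums)
        d = patterson_d(sums)
        key = (s2, s1, s3) if swapped else (s1, s2, s3)
        d_by_arr[key] = d
        if d is not None and (best is None or d < best[0]):
            best = (d, key, sums)
    if best is None:
        return TrioResult(a, b, c, outgroup, d_by_arr, None, None, None)
    dmin, (p1, p2, p3), sums = best
    z, p_raw = jackknife_significance(sums)
    return TrioResult(p1, p2, p3, outgroup, d_by_arr, dmin, z, p_raw)


def trio_morph_group(trio: TrioResult, sheet: SampleSheet) -> MorphGroup:
    """Wing-colour grouping of the introgressing (P2, P3) species pair."""
    morphs = {sheet.morph_of_species(trio.p2), sheet.morph_of_species(trio.p3)}
    if Morph.unknown in morphs:
        return MorphGroup.undefined
    if morphs == {Morph.alba}:
        return MorphGroup.AlbaAlba
    if morphs == {Morph.colored}:
        return MorphGroup.ColoredColored
    return MorphGroup.AlbaColored


def enumerate_trios(
    geno: GenotypeMatrix,
    sheet: SampleSheet,
    outgroup: str,
    species: list[str] | None = None,
    alpha: float = 0.05,
    n_blocks: int = DEFAULT_JACKKNIFE_BLOCKS,
    alba_only_species: list[str] | None = None,
) -> list[TrioResult]:
    """All C(n, 3) ingroup trios with D, Dmin, jackknife Z and Holm p.

    ``alba_only_species`` lists polymorphic species for which only
    Alba-morph samples should be used.
    """
    if species is None:
        species = [s for s in sheet.species() if s != outgroup]
    if len(species) < 3:
        raise ValueError("need >= 3 ingroup species")
    species_samples: dict[str, list[str]] = {}
    for sp in list(species) + [outgroup]:
        morph = Morph.alba if alba_only_species and sp in alba_only_species else None
        ids = sheet.samples_for_species(sp, morph)
        ids = [s for s in ids if s in geno.samples]
        if not ids:
            raise ValueError(f"species {sp!r} has no usable samples")
        species_samples[sp] = ids
    results = [
        evaluate_trio(geno, species_samples, trio, outgroup, n_blocks)
        for trio in itertools.combinations(species, 3)
    ]
    defined = [r for r in results if r.p_raw is not None]
    if defined:
        adj = holm_correct([r.p_raw for r in defined])
        for r, a in zip(defined, adj):
            r.p_holm = float(a)
    for r in results:
        r.morph_group = trio_morph_group(r, sheet)
    return results


# ---------------------------------------------------------------------------
# f4-ratio and f-branch
# ---------------------------------------------------------------------------

def f4_ratio(
    geno: GenotypeMatrix,
    p1: list[str],
    p2: list[str],
    p3: list[str],
    outgroup: list[str],
) -> float | None:
    """Admixture-fraction estimate f = S(P1,P2,P3,O) / S(P1,P3,P3,O).

    The denominator substitutes the donor P3 for P2 using an unbiased
    within-population estimator of p3^2 (sampling without replacement), so
    a single donor population can stand in for both donor slots.
    """
    freqs = np.column_stack(
        [geno.alt_freqs(pop) for pop in (p1, p2, p3, outgroup)]
    )
    alt3, n3 = geno.alt_counts(p3)
    usable = ~np.isnan(freqs).any(axis=1) & (freqs[:, 3] != 0.5) & (n3 >= 2)
    f = freqs[usable]
    alt3, n3 = alt3[usable], n3[usable]
    flip = f[:, 3] > 0.5
    f[flip] = 1.0 - f[flip]
    alt3 = np.where(flip, n3 - alt3, alt3)
    if len(f) == 0:
        return None
    abba, baba = _abba_baba(f)
    numerator = (abba - baba).sum()
    # unbiased estimates of p3^2 and p3 (1 - p3)
    p3sq = alt3 * (alt3 - 1) / (n3 * (n3 - 1))
    p3q3 = alt3 * (n3 - alt3) / (n3 * (n3 - 1))
    p1f, p4f = f[:, 0], f[:, 3]
    abba_d = (1 - p1f) * p3sq * (1 - p4f)
    baba_d = p1f * p3q3 * (1 - p4f)
    denominator = (abba_d - baba_d).sum()
    if denominator == 0:
        return None
    return float(numerator / denominator)


@dataclass
class FBranchMatrix:
    """f-branch values: rows = tree branches, columns = donor species."""

    branches: list[Branch]
    species: list[str]
    values: np.ndarray  # (n_branches, n_species), NaN where inadmissible

    def clamped(self) -> np.ndarray:
        """Display view with negative values clamped to zero."""
        v = self.values.copy()
        v[np.isfinite(v) & (v < 0)] = 0.0
        return v

    def cell(self, branch_label: str, species: str) -> float:
        i = [b.label for b in self.branches].index(branch_label)
        j = self.species.index(species)
        return float(self.values[i, j])

    def max_cell(self) -> tuple[str, str, float]:
        v = np.where(np.isfinite(self.values), self.values, -np.inf)
        i, j = np.unravel_index(np.argmax(v), v.shape)
        return self.branches[i].label, self.species[j], float(v[i, j])


def f_branch(
    tree: SpeciesTree,
    geno: GenotypeMatrix,
    species_samples: dict[str, list[str]],
    outgroup: str,
) -> FBranchMatrix:
    """f-branch decomposition of excess derived-allele sharing.

    For a branch b (with sister clade S) and a candidate donor species C
    not descended from b, f_b(C) is the median over recipients a in
    descendants(b) of the minimum over proxies A in S \\ {C} of the
    f4-ratio f(A, a; C, O) — the minimum makes the attribution
    conservative, the median robust. Cells that are topologically
    inadmissible are NaN.
    """
    if outgroup not in tree.leaf_labels:
        raise ValueError(f"outgroup {outgroup!r} not a tree leaf")
    branches = tree.branches(exclude_root_children_of_outgroup=outgroup)
    columns = [s for s in tree.leaf_labels if s != outgroup]
    values = np.full((len(branches), len(columns)), np.nan)
    cache: dict[tuple[str, str, str], float | None] = {}

    def f(a_proxy: str, recipient: str, donor: str) -> float | None:
        key = (a_proxy, recipient, donor)
        if key not in cache:
            cache[key] = f4_ratio(
                geno,
                species_samples[a_proxy],
                species_samples[recipient],
                species_samples[donor],
                species_samples[outgroup],
            )
        return cache[key]

    for i, br in enumerate(branches):
        for j, donor in enumerate(columns):
            if donor in br.leaves:
                continue
            proxies = [s for s in br.sister_leaves if s != donor]
            if not proxies:
                continue
            medians: list[float] = []
            for recipient in br.leaves:
                vals = [f(a, recipient, donor) for a in proxies]
                vals = [v for v in vals if v is not None]
                if vals:
                    medians.append(min(vals))
            if medians:
                values[i, j] = float(np.median(medians))
    return FBranchMatrix(branches=branches, species=columns, values=values)


# ---------------------------------------------------------------------------
# Windowed scans
# ---------------------------------------------------------------------------

def _fdm_denominator(p: np.ndarray) -> np.ndarray:
    """Per-site f_dM denominator (donor-maximised, symmetric in P1/P2)."""
    p1, p2, p3, p4 = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    out = np.empty(len(p))
    case2 = p2 >= p1
    pd = np.maximum(p2, p3)
    out[case2] = (pd * (1 - p4) * (pd - p1))[case2]
    pd = np.maximum(p1, p3)
    out[~case2] = (pd * (1 - p4) * (pd - p2))[~case2]
    return out


def window_scan(
    geno: GenotypeMatrix,
    p1: list[str],
    p2: list[str],
    p3: list[str],
    outgroup: list[str],
    snps_per_window: int = SNPS_PER_WINDOW,
) -> dict[str, list[WindowStat]]:
    """Windowed d_f and f_dM over non-overlapping blocks of usable SNPs.

    f_dM is the dynamic-donor modification of the f_d estimator: the
    shared numerator sum(ABBA - BABA) over a per-site denominator that
    substitutes the larger of the P2/P3 (or P1/P3) frequencies for both
    donor slots, signed so the statistic lies in [-1, 1] and is positive
    for P2-P3 sharing.

    d_f is the distance fraction: sum(ABBA - BABA) over
    sum(ABBA - BABA) + 2 * sum(dxy(P2, P3)), i.e. the share of the
    P2-P3 divergence attributable to introgression. It is bounded above by
    1, has expectation 0 under symmetric divergence, and is positive under
    P2-P3 gene flow; because the normalisation uses absolute divergence it
    stays informative for old introgression events.

    Windows whose denominator vanishes are flagged undefined.
    """
    if snps_per_window <= 0:
        raise ValueError("snps_per_window must be > 0")
    pf = polarised_freqs(geno, p1, p2, p3, outgroup)
    out: dict[str, list[WindowStat]] = {"d_f": [], "f_dM": []}
    if pf.n_sites < snps_per_window:
        logger.warning(
            "window_scan: only %d usable SNPs (< one window of %d)",
            pf.n_sites, snps_per_window,
        )
        return out
    for chrom in dict.fromkeys(pf.chrom.tolist()):
        sel = pf.chrom == chrom
        p = pf.p[sel]
        pos = pf.pos[sel]
        n_full = len(pos) // snps_per_window
        for k in range(n_full):
            sl = slice(k * snps_per_window, (k + 1) * snps_per_window)
            pw = p[sl]
            win = WindowSpec(
                chrom, int(pos[sl][0]), int(pos[sl][-1]) + 1, WindowMode.snp_count
            )
            abba, baba = _abba_baba(pw)
            num = (abba - baba).sum()
            dxy23 = (pw[:, 1] * (1 - pw[:, 2]) + pw[:, 2] * (1 - pw[:, 1])).sum()
            df_den = num + 2.0 * dxy23
            df_val = float(num / df_den) if df_den > 0 else None
            out["d_f"].append(WindowStat(win, "d_f", df_val, snps_per_window))
            fdm_den = _fdm_denominator(pw).sum()
            fdm_val = float(num / fdm_den) if fdm_den > 0 else None
            out["f_dM"].append(WindowStat(win, "f_dM", fdm_val, snps_per_window))
    return out


# ---------------------------------------------------------------------------
# Locus outlier enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    groups: list[MorphGroup]
    table: np.ndarray  # (n_groups, 2): outlier / non-outlier counts
    chi2: float
    df: int
    p: float


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail chi-squared probability (for df = 2, exp(-x/2) exactly)."""
    if x < 0:
        raise ValueError("chi-squared statistic must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(x, df))


def chisq_homogeneity(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of homogeneity on a groups x 2 table."""
    table = np.asarray(table, dtype=float)
    chi2, _, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), chisq_sf(float(chi2), int(df))


def locus_is_outlier(
    d_f_windows: list[WindowStat],
    locus: tuple[str, int, int],
    percentile: float = 95.0,
    aggregation: str = "any",
) -> bool | None:
    """Whether a trio's d_f at the locus exceeds its chromosome percentile.

    The threshold is the ``percentile`` of the trio's defined windows on
    the locus chromosome. ``aggregation`` = "any" calls the locus an
    outlier if any overlapping window exceeds the threshold; "all"
    requires every overlapping window to. Returns None when no defined
    window overlaps the locus.
    """
    chrom, start, end = locus
    on_chrom = [w for w in d_f_windows if w.window.chrom == chrom and w.defined]
    if not on_chrom:
        return None
    threshold = np.percentile([w.value for w in on_chrom], percentile)
    over = [w for w in on_chrom if w.window.overlaps(chrom, start, end)]
    if not over:
        return None
    flags = [w.value > threshold for w in over]
    return all(flags) if aggregation == "all" else any(flags)


def alba_outlier_enrichment(
    scans: dict[str, list[WindowStat]],
    groups: dict[str, MorphGroup],
    locus: tuple[str, int, int],
    percentile: float = 95.0,
    aggregation: str = "any",
) -> EnrichmentResult:
    """Cross-tabulate locus outlier status by morph group; Pearson chi2.

    ``scans`` maps a trio key to its d_f window list; ``groups`` maps the
    same keys to morph groups. Groups without any classifiable trio are
    dropped (with a warning) and the degrees of freedom adjusted.
    """
    counts: dict[MorphGroup, list[int]] = {}
    for key, windows in scans.items():
        group = groups[key]
        if group is MorphGroup.undefined:
            continue
        flag = locus_is_outlier(windows, locus, percentile, aggregation)
        if flag is None:
            continue
        row = counts.setdefault(group, [0, 0])
        row[0 if flag else 1] += 1
    kept = [g for g in counts if sum(counts[g]) > 0]
    dropped = [
        g
        for g in (MorphGroup.AlbaAlba, MorphGroup.AlbaColored, MorphGroup.ColoredColored)
        if g not in kept
    ]
    if dropped:
        logger.warning("enrichment: dropping empty groups %s", [g.value for g in dropped])
    if len(kept) < 2:
        raise ValueError("need >= 2 non-empty morph groups for the test")
    table = np.asarray([counts[g] for g in kept], dtype=float)
    chi2, df, p = chisq_homogeneity(table)
    return EnrichmentResult(groups=kept, table=table, chi2=chi2, df=df, p=p)
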