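"""Windowed divergence statistics and the relative node depth (RND) scan.

d_XY is the mean pairwise difference per callable site between two
populations, computed comparison-wise (only non-missing allele pairs
counted) with an all-sites callable denominator. RND divides the focal
pair's d_XY by the mean of each focal population's d_XY to a shared
outgroup, cancelling local mutation-rate variation; introgressed tracts
show up as low-RND outliers. Windowed nucleotide diversity and Tajima's D
use the canonical constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix, WindowSpec, WindowStat


@dataclass
class RNDResult:
    """Relative node depth for one window."""

    window: WindowSpec
    d_xy: float
    d_xo: float
    d_yo: float

    @property
    def rnd(self) -> float | None:
        denom = (self.d_xo + self.d_yo) / 2.0
        if denom == 0:
            return None
        return self.d_xy / denom


def _dxy_site_terms(geno: GenotypeMatrix, pop_x: list[str], pop_y: list[str]) -> np.ndarray:
    """Per-site mean pairwise difference between X and Y chromosomes.

    Comparison-wise missing-data handling: cX(nY-cY) + cY(nX-cX) differing
    pairs out of nX*nY cross-population pairs of non-missing chromosomes;
    NaN where either population has no calls.
    """
    if not pop_x or not pop_y:
        raise ValueError("both populations need >= 1 sample")
    cx, nx = geno.alt_counts(pop_x)
    cy, ny = geno.alt_counts(pop_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (cx * (ny - cy) + cy * (nx - cx)) / (nx * ny)
    d[(nx == 0) | (ny == 0)] = np.nan
    return d


def _window_index(geno: GenotypeMatrix, windows: list[WindowSpec]) -> list[np.ndarray]:
    """Site indices falling in each window."""
    out = []
    for w in windows:
        sel = (geno.chrom == w.chrom) & (geno.pos >= w.start) & (geno.pos < w.end)
        out.append(np.flatnonzero(sel))
    return out


def _callable_count(geno: GenotypeMatrix, w: WindowSpec,
                    callable_counts: dict[tuple[str, int, int], int] | None) -> int:
    if callable_counts is not None:
        return callable_counts.get((w.chrom, w.start, w.end), 0)
    if geno.callable_sites is not None:
        return geno.callable_sites.get((w.chrom, w.start, w.end), 0)
    return 0


def dxy_windows(
    geno: GenotypeMatrix,
    pop_x: list[str],
    pop_y: list[str],
    windows: list[WindowSpec],
    callable_counts: dict[tuple[str, int, int], int] | None = None,
) -> list[WindowStat]:
    """Windowed absolute divergence d_XY per callable site.

    Variant sites contribute their mean pairwise difference; invariant
    callable sites contribute zero, so the denominator is the all-sites
    callable count per window. Windows with no callable sites are flagged
    undefined.
    """
    d = _dxy_site_terms(geno, pop_x, pop_y)
    stats: list[WindowStat] = []
    for w, idx in zip(windows, _window_index(geno, windows)):
        n_callable = _callable_count(geno, w, callable_counts)
        terms = d[idx]
        terms = terms[~np.isnan(terms)]
        if n_callable <= 0:
            stats.append(WindowStat(w, "d_xy", None, 0))
            continue
        stats.append(WindowStat(w, "d_xy", float(terms.sum()) / n_callable, n_callable))
    return stats


def rnd_windows(
    dxy_xy: list[WindowStat],
    dxy_xo: list[WindowStat],
    dxy_yo: list[WindowStat],
) -> list[RNDResult]:
    """Combine aligned d_XY series into RND; drop undefined windows.

    Windows where any input is undefined or where d_XO + d_YO = 0 (the
    'infinite values' of the scan) are removed.
    """
    if not (len(dxy_xy) == len(dxy_xo) == len(dxy_yo)):
        raise ValueError("window series must have equal length")
    out: list[RNDResult] = []
    for a, b, c in zip(dxy_xy, dxy_xo, dxy_yo):
        if not (a.window == b.window == c.window):
            raise ValueError(f"misaligned windows: {a.window} / {b.window} / {c.window}")
        if not (a.defined and b.defined and c.defined):
            continue
        r = RNDResult(a.window, a.value, b.value, c.value)
        if r.rnd is None:
            continue
        out.append(r)
    return out


def quantile_threshold(values: list[float] | np.ndarray, q: float) -> float:
    """Empirical quantile with linear interpolation (type-7).

    Values at or below the threshold are the lower-tail outlier calls of
    the RND scan.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("no values for quantile")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(values, q, method="linear"))


@dataclass
class TajimaComponents:
    """Tajima's D with its canonical intermediate constants."""

    n: int  # chromosomes
    s: int  # segregating sites
    pi: float  # sum over sites of mean pairwise diversity
    window: WindowSpec | None = None

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("Tajima's D needs >= 4 chromosomes")
        n = self.n
        self.a1 = sum(1.0 / i for i in range(1, n))
        self.a2 = sum(1.0 / i**2 for i in range(1, n))
        self.b1 = (n + 1) / (3.0 * (n - 1))
        self.b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        self.c1 = self.b1 - 1.0 / self.a1
        self.c2 = self.b2 - (n + 2) / (self.a1 * n) + self.a2 / self.a1**2
        self.e1 = self.c1 / self.a1
        self.e2 = self.c2 / (self.a1**2 + self.a2)

    @property
    def d(self) -> float | None:
        if self.s == 0:
            return None
        var = self.e1 * self.s + self.e2 * self.s * (self.s - 1)
        return (self.pi - self.s / self.a1) / math.sqrt(var)


def tajimas_d(
    geno: GenotypeMatrix,
    pop: list[str],
    windows: list[WindowSpec],
) -> list[TajimaComponents | None]:
    """Windowed Tajima's D for one population.

    Uses fully-called sites only (a site with any missing call in the
    population is excluded) so the chromosome count n is constant. Windows
    return None when fewer than 4 chromosomes are available.
    """
    idx = geno.sample_indices(pop)
    g = geno.genotypes[:, idx]
    full = (g != -1).all(axis=1)
    n = 2 * len(pop)
    if n < 4:
        raise ValueError("Tajima's D needs >= 2 diploids")
    alt = np.where(full, g.clip(min=0).sum(axis=1), 0)
    seg = full & (alt > 0) & (alt < n)
    # per-site heterozygosity (unbiased): 2 c (n - c) / (n (n - 1))
    h = 2.0 * alt * (n - alt) / (n * (n - 1))
    out: list[TajimaComponents | None] = []
    for w, site_idx in zip(windows, _window_index(geno, windows)):
        sel = site_idx[seg[site_idx]]
        out.append(
            TajimaComponents(n=n, s=int(len(sel)), pi=float(h[sel].sum()), window=w)
        )
    return out


def pi_windows(
    geno: GenotypeMatrix,
    pop: list[str],
    windows: list[WindowSpec],
    callable_counts: dict[tuple[str, int, int], int] | None = None,
) -> list[WindowStat]:
    """Windowed nucleotide diversity per callable site (comparison-wise)."""
    c, n = geno.alt_counts(pop)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 2.0 * c * (n - c) / (n * (n - 1))
    h[n < 2] = np.nan
    out: list[WindowStat] = []
    for w, idx in zip(windows, _window_index(geno, windows)):
        n_callable = _callable_count(geno, w, callable_counts)
        if n_callable <= 0:
            out.append(WindowStat(w, "pi", None, 0))
            continue
        terms = h[idx]
        terms = terms[~np.isnan(terms)]
        out.append(WindowStat(w, "pi", float(terms.sum()) / n_callable, n_callable))
    return out


def fixed_difference_identity(n_fixed: int, alignment_length: int) -> tuple[float, int]:
    """Percent identity from fixed differences over an alignment.

    Returns the exact percentage and its integer-percent presentation.
    """
    if alignment_length <= 0:
        raise ValueError("alignment length must be > 0")
    if not 0 <= n_fixed <= alignment_length:
        raise ValueError("fixed differences must lie in [0, length]")
    pct = 100.0 * (1.0 - n_fixed / alignment_length)
    return pct, int(round(pct))
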