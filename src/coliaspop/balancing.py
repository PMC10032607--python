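"""Folded indel frequency-spectrum test for balancing selection.

A balanced polymorphism should segregate at a frequency far above what
comparable neutral variants reach. The test compares the Alba allele
frequency — obtained from field phenotype counts via the Hardy-Weinberg
dominant-allele conversion — against the folded allele frequency spectrum
of high-confidence intergenic insertions/deletions genotyped in the same
population sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import MISSING, PhenotypeCounts, SVTable, SVType

logger = logging.getLogger(__name__)


def filter_sv(
    table: SVTable,
    gene_intervals: list[tuple[str, int, int]] | None = None,
    min_gq: float = 20.0,
) -> SVTable:
    """High-confidence intergenic indel filter.

    Retains records that are INS/DEL, pass-flagged, fully genotyped (no
    missing call), with every genotype quality >= ``min_gq``, and not
    overlapping any gene interval (BED, 0-based half-open; the record span
    is [pos-1, pos-1+length)). Per-rule removal counts are logged.
    """
    n = table.n_records
    is_indel = np.asarray([t in (SVType.INS, SVType.DEL) for t in table.sv_type])
    passed = table.filter_pass.copy()
    no_missing = (table.genotypes != MISSING).all(axis=1)
    gq_ok = np.nan_to_num(table.gq, nan=-1.0).min(axis=1) >= min_gq if n else np.ones(0, bool)
    intergenic = np.ones(n, dtype=bool)
    if gene_intervals:
        start = table.pos - 1
        end = start + np.maximum(table.length, 1)
        for g_chrom, g_start, g_end in gene_intervals:
            hit = (table.chrom == g_chrom) & (start < g_end) & (g_start < end)
            intergenic &= ~hit
    keep = is_indel & passed & no_missing & gq_ok & intergenic
    logger.info(
        "filter_sv: %d/%d retained (non-indel %d, non-pass %d, missing-gt %d, "
        "low-GQ %d, genic %d)",
        int(keep.sum()), n, int((~is_indel).sum()), int((~passed).sum()),
        int((~no_missing).sum()), int((~gq_ok).sum()), int((~intergenic).sum()),
    )
    return table.subset(keep)


def fold(freq: float | np.ndarray) -> float | np.ndarray:
    """Minor-allele (folded) frequency: min(f, 1 - f)."""
    return np.minimum(freq, 1.0 - freq)


def folded_afs(table: SVTable) -> np.ndarray:
    """Folded allele frequency of each record over non-missing diploids.

    Records with no non-missing genotype are excluded with a warning.
    """
    ok = table.genotypes != MISSING
    n_chrom = 2 * ok.sum(axis=1)
    alt = np.where(ok, table.genotypes, 0).sum(axis=1)
    usable = n_chrom > 0
    if (~usable).any():
        logger.warning("folded_afs: excluding %d all-missing records", int((~usable).sum()))
    if not usable.any():
        raise ValueError("no record with a non-missing genotype")
    f = alt[usable] / n_chrom[usable]
    return np.asarray(fold(f), dtype=float)


def hw_dominant_allele_freq(phenotype_freq: float) -> float:
    """Allele frequency of a dominant allele from its phenotype frequency.

    Under Hardy-Weinberg, a dominant phenotype at frequency f = q^2 +
    2q(1-q) = 1 - (1-q)^2 implies q = 1 - sqrt(1 - f).
    """
    if not 0.0 <= phenotype_freq < 1.0:
        raise ValueError("phenotype frequency must be in [0, 1)")
    return 1.0 - math.sqrt(1.0 - phenotype_freq)


@dataclass
class PopulationVerdict:
    population: str
    n_females: int
    phenotype_freq: float
    q_alba: float
    empirical_p: float  # fraction of indels with folded frequency >= q_alba
    empirical_p_plus_one: float  # conservative (count+1)/(n+1) variant
    exceeds_background: bool


@dataclass
class BalancingTestResult:
    """Folded AFS background vs per-population Alba allele frequencies."""

    afs: np.ndarray
    percentile: float
    threshold: float
    verdicts: list[PopulationVerdict]


def balancing_test(
    afs: np.ndarray,
    phenotype_counts: list[PhenotypeCounts],
    percentile: float = 95.0,
) -> BalancingTestResult:
    """Compare Alba allele frequencies with the genome-wide indel AFS.

    The background threshold is the empirical ``percentile`` quantile of
    the folded AFS. Each population's Alba allele frequency q (from the
    Hardy-Weinberg dominant conversion of its phenotype frequency) gets an
    empirical p — the fraction of indels at folded frequency >= q — and a
    verdict: q exceeds the background iff q > threshold.
    """
    afs = np.asarray(afs, dtype=float)
    if len(afs) == 0:
        raise ValueError("empty allele frequency spectrum")
    if (afs > 0.5).any():
        raise ValueError("folded frequencies cannot exceed 0.5")
    threshold = float(np.percentile(afs, percentile))
    n = len(afs)
    verdicts = []
    for pc in phenotype_counts:
        q = hw_dominant_allele_freq(pc.phenotype_freq)
        if q > 0.5:
            raise ValueError(
                f"population {pc.population!r}: allele frequency {q:.3f} > 0.5 "
                "cannot be compared with a folded spectrum"
            )
        count = int((afs >= q).sum())
        verdicts.append(
            PopulationVerdict(
                population=pc.population,
                n_females=pc.n_total,
                phenotype_freq=pc.phenotype_freq,
                q_alba=q,
                empirical_p=count / n,
                empirical_p_plus_one=(count + 1) / (n + 1),
                exceeds_background=q > threshold,
            )
        )
    return BalancingTestResult(
        afs=afs, percentile=percentile, threshold=threshold, verdicts=verdicts
    )
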