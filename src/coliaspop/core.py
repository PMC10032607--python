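"""Shared domain containers for the pipeline.

All internal coordinates are 0-based half-open; VCF positions (1-based) are
converted on read (``pos_internal = pos_vcf - 1``) and back on write.
Genotypes are stored as diploid alt-allele dosages in {0, 1, 2} with -1 for
missing calls.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MISSING = -1


class Region(str, enum.Enum):
    SouthAmerica = "SouthAmerica"
    NorthAmerica = "NorthAmerica"
    Holarctic = "Holarctic"
    EurasiaAfrica = "EurasiaAfrica"
    unknown = "unknown"


class Morph(str, enum.Enum):
    alba = "alba"
    colored = "colored"
    unknown = "unknown"


class MorphGroup(str, enum.Enum):
    """Wing-colour pairing of the P2/P3 species of a trio."""

    AlbaAlba = "AlbaAlba"
    AlbaColored = "AlbaColored"
    ColoredColored = "ColoredColored"
    undefined = "undefined"


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    species: str
    region: Region = Region.unknown
    morph: Morph = Morph.unknown
    population: str | None = None


class SampleSheet:
    """Sample metadata: species, geographic region, wing-colour morph.

    Sample ids must be unique; lookups by species return samples in sheet
    order.
    """

    def __init__(self, samples: Iterable[SampleInfo]):
        self.samples = list(samples)
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValueError(f"duplicate sample_id: {s.sample_id!r}")
            seen.add(s.sample_id)
        self._by_id = {s.sample_id: s for s in self.samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> SampleInfo:
        return self._by_id[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def species_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].species

    def samples_for_species(self, species: str, morph: Morph | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.species == species and (morph is None or s.morph == morph)
        ]

    def species(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.species not in out:
                out.append(s.species)
        return out

    def morph_of_species(self, species: str) -> Morph:
        """Morph label for a species: unanimous sample morph or unknown."""
        morphs = {s.morph for s in self.samples if s.species == species}
        morphs.discard(Morph.unknown)
        if len(morphs) == 1:
            return morphs.pop()
        return Morph.unknown


@dataclass
class GenotypeMatrix:
    """Biallelic-SNP genotypes: sites x samples alt-allele dosages.

    ``pos`` is 0-based (converted from VCF on read). ``genotypes`` has shape
    (n_sites, n_samples), dtype int8, values {0, 1, 2, MISSING}.
    ``callable_sites`` optionally carries per-window callable-site counts
    (the all-sites denominator for absolute divergence).
    """

    chrom: np.ndarray  # object/str per site
    pos: np.ndarray  # int64, 0-based
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray  # int8 (n_sites, n_samples)
    samples: list[str]
    callable_sites: dict[tuple[str, int, int], int] | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype values must be in {0, 1, 2, missing}")
        for c in self.chroms():
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chroms(self) -> list[str]:
        out: list[str] = []
        for c in self.chrom:
            if c not in out:
                out.append(c)
        return out

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing}")
        return np.asarray([lookup[s] for s in sample_ids], dtype=np.intp)

    def alt_counts(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Per-site alt-allele count and non-missing chromosome count."""
        idx = self.sample_indices(sample_ids)
        g = self.genotypes[:, idx]
        ok = g != MISSING
        alt = np.where(ok, g, 0).sum(axis=1)
        n = 2 * ok.sum(axis=1)
        return alt.astype(np.int64), n.astype(np.int64)

    def alt_freqs(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Per-site alt frequency over non-missing calls; NaN if none."""
        alt, n = self.alt_counts(sample_ids)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=np.asarray(self.ref)[mask],
            alt=np.asarray(self.alt)[mask],
            genotypes=self.genotypes[mask],
            samples=list(self.samples),
            callable_sites=self.callable_sites,
        )


class WindowMode(str, enum.Enum):
    bp = "bp"
    snp_count = "snp_count"


@dataclass(frozen=True)
class WindowSpec:
    """Genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int
    mode: WindowMode = WindowMode.bp

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window start {self.start} must be < end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class WindowStat:
    """One named statistic in one window.

    ``value`` is None when the statistic's denominator vanished — undefined
    windows are flagged, never silently reported as zero.
    """

    window: WindowSpec
    stat_name: str
    value: float | None
    n_sites: int = 0

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class DepthTrack:
    """Per-sample read-depth intervals with BedGraph semantics."""

    sample_id: str
    chrom: np.ndarray
    start: np.ndarray  # int64, 0-based
    end: np.ndarray  # int64, exclusive
    depth: np.ndarray  # float64, >= 0

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if (self.depth < 0).any():
            raise ValueError("depth must be >= 0")
        if (self.end <= self.start).any():
            raise ValueError("intervals must have end > start")
        for c in set(self.chrom.tolist()):
            sel = self.chrom == c
            s, e = self.start[sel], self.end[sel]
            order = np.argsort(s, kind="stable")
            s, e = s[order], e[order]
            if (s[1:] < e[:-1]).any():
                raise ValueError(f"overlapping intervals on {c}")

    def total_depth(self) -> float:
        """Sum of depth x interval length (per-base depth mass)."""
        return float(np.sum(self.depth * (self.end - self.start)))


class SVType(str, enum.Enum):
    INS = "INS"
    DEL = "DEL"


@dataclass
class SVTable:
    """Structural-variant (insertion/deletion) records with genotypes.

    ``genotypes`` and ``gq`` have shape (n_records, n_samples); genotype
    values in {0, 1, 2, MISSING}.
    """

    chrom: np.ndarray
    pos: np.ndarray  # int64, 1-based as in VCF
    sv_type: np.ndarray  # object of SVType values
    length: np.ndarray  # int64
    filter_pass: np.ndarray  # bool
    genotypes: np.ndarray  # int8
    gq: np.ndarray  # float64
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sv_type = np.asarray(self.sv_type, dtype=object)
        self.length = np.asarray(self.length, dtype=np.int64)
        self.filter_pass = np.asarray(self.filter_pass, dtype=bool)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.gq = np.asarray(self.gq, dtype=np.float64)

    @property
    def n_records(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, mask: np.ndarray) -> "SVTable":
        return SVTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            sv_type=self.sv_type[mask],
            length=self.length[mask],
            filter_pass=self.filter_pass[mask],
            genotypes=self.genotypes[mask],
            gq=self.gq[mask],
            samples=list(self.samples),
        )


@dataclass
class PhenotypeCounts:
    """Counts of Alba vs coloured females in one field population."""

    population: str
    n_alba: int
    n_colored: int

    def __post_init__(self) -> None:
        if self.n_alba < 0 or self.n_colored < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_alba + self.n_colored

    @property
    def phenotype_freq(self) -> float:
        if self.n_total == 0:
            raise ValueError("phenotype frequency undefined with zero females")
        return self.n_alba / self.n_total
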