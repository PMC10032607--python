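"""Genome-wide coverage x wing-colour segregation scan.

For every window, read coverage of each species is reduced to a binary
presence call; the mean presence among Alba species (A_mean) and among
coloured species (O_mean) and their difference (the colour bias) identify
windows whose coverage segregates with the morph. A bias of +1 means every
Alba species is covered and no coloured species is; the Alba candidate
insertion is expected to be such a window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import DepthTrack, Morph, SampleSheet, WindowSpec

logger = logging.getLogger(__name__)


@dataclass
class CoverageMatrix:
    """Binary presence of read coverage per (species, window)."""

    windows: list[WindowSpec]
    species: list[str]
    morphs: list[Morph]
    presence: np.ndarray  # bool, (n_species, n_windows)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.species), len(self.windows)):
            raise ValueError("presence shape must be (n_species, n_windows)")
        if len(self.morphs) != len(self.species):
            raise ValueError("one morph label per species required")


@dataclass
class CoverageStat:
    """Mean presence by morph class in one window and their difference."""

    window: WindowSpec
    a_mean: float
    o_mean: float

    @property
    def bias(self) -> float:
        return self.a_mean - self.o_mean


def window_covered_fraction(track: DepthTrack, windows: list[WindowSpec],
                            min_depth: float = 1.0) -> np.ndarray:
    """Fraction of each window's bases with depth >= min_depth."""
    out = np.zeros(len(windows))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in set(track.chrom.tolist()):
        sel = (track.chrom == c) & (track.depth >= min_depth)
        by_chrom[c] = (track.start[sel], track.end[sel])
    warned = False
    for i, w in enumerate(windows):
        if w.chrom not in by_chrom:
            if not warned:
                logger.warning(
                    "track %s has no data for %s; treating as depth 0",
                    track.sample_id, w.chrom,
                )
                warned = True
            continue
        s, e = by_chrom[w.chrom]
        ov = np.minimum(e, w.end) - np.maximum(s, w.start)
        out[i] = np.sum(ov[ov > 0]) / w.length
    return out


def presence_matrix(
    depth_tracks: list[DepthTrack],
    windows: list[WindowSpec],
    sheet: SampleSheet,
    min_depth: float = 1.0,
    min_covered_fraction: float = 0.5,
) -> CoverageMatrix:
    """Binary coverage presence per species: covered fraction >= threshold.

    Species with multiple samples are collapsed with a logical OR across
    their tracks. Species keep their sheet morph label; the downstream scan
    excludes unknown-morph species.
    """
    species: list[str] = []
    morphs: list[Morph] = []
    rows: list[np.ndarray] = []
    tracks_by_species: dict[str, list[DepthTrack]] = {}
    for tr in depth_tracks:
        sp = sheet.species_of(tr.sample_id)
        tracks_by_species.setdefault(sp, []).append(tr)
    for sp, trs in tracks_by_species.items():
        present = np.zeros(len(windows), dtype=bool)
        for tr in trs:
            frac = window_covered_fraction(tr, windows, min_depth)
            present |= frac >= min_covered_fraction
        species.append(sp)
        morphs.append(sheet.morph_of_species(sp))
        rows.append(present)
    return CoverageMatrix(windows, species, morphs, np.vstack(rows))


def color_bias_scan(matrix: CoverageMatrix) -> list[CoverageStat]:
    """Per-window A_mean, O_mean and their difference (the colour bias)."""
    alba = np.asarray([m == Morph.alba for m in matrix.morphs])
    colored = np.asarray([m == Morph.colored for m in matrix.morphs])
    if not alba.any() or not colored.any():
        raise ValueError("colour bias needs >= 1 alba and >= 1 colored species")
    a_means = matrix.presence[alba].mean(axis=0)
    o_means = matrix.presence[colored].mean(axis=0)
    return [
        CoverageStat(w, float(a), float(o))
        for w, a, o in zip(matrix.windows, a_means, o_means)
    ]


def segregating_windows(stats: list[CoverageStat], tol: float = 0.0) -> list[tuple[WindowSpec, float]]:
    """Windows whose |bias| >= 1 - tol, with the signed bias."""
    return [(s.window, s.bias) for s in stats if abs(s.bias) >= 1.0 - tol]


def bias_histogram(stats: list[CoverageStat], bin_width: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of biases over [-1, 1]; counts sum to the window count."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not stats:
        raise ValueError("no coverage statistics to bin")
    n_bins = int(np.ceil(2.0 / bin_width))
    edges = -1.0 + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], 1.0)
    values = np.asarray([s.bias for s in stats])
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts
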