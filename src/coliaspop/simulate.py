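"""Synthetic-data generators with ground truth for every pipeline stage.

Each generator emulates the statistical structure one analysis assumes:

* :func:`simulate_quartet` — per-site coalescent genotypes for a species
  quartet (((P1,P2),P3),O) with an optional admixture pulse of fraction
  gamma, exercising the D / f4-ratio / windowed-scan estimators;
* :func:`simulate_species_tree_5taxa` — the same machinery for a 5-taxon
  tree with gene flow into an ancestral branch, exercising f-branch;
* :func:`simulate_rnd_scenario` — two ingroups plus an outgroup with an
  introgressed tract of reduced between-ingroup divergence, exercising the
  relative-node-depth scan;
* :func:`simulate_coverage` — a binary species x window coverage matrix
  with one window whose coverage segregates perfectly with morph;
* :func:`simulate_sv_table` — an indel table with a neutral-like folded
  frequency spectrum plus one planted high-frequency (balanced) record.

All generators are deterministic given their seed, and return a
:class:`SimTruth` describing exactly what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._coalescent import EV_MERGE, EV_PULSE, simulate_site_masks
from .core import (
    GenotypeMatrix,
    Morph,
    SampleInfo,
    SampleSheet,
    SVTable,
    SVType,
    WindowSpec,
)
from .coverage import CoverageMatrix

SIM_CHROM = "sim_1"


@dataclass
class QuartetSimParams:
    """Coalescent parameters for the quartet generator.

    Times are in coalescent units (2N generations) and must satisfy
    0 < t_gf < t12 < t123 < t_root. ``gamma`` is the admixture-pulse
    fraction: at time ``t_gf`` the recipient population's lineages move
    (backwards in time) into P3 with that probability, independently per
    site. ``theta`` is the per-site scaled mutation rate.
    """

    t_gf: float = 0.1
    t12: float = 1.0
    t123: float = 2.0
    t_root: float = 3.0
    gamma: float = 0.0
    direction: str = "P3->P2"
    samples_per_pop: int = 2  # diploids per population
    n_sites: int = 50_000
    theta: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.t_gf < self.t12 < self.t123 < self.t_root):
            raise ValueError("need 0 < t_gf < t12 < t123 < t_root")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be > 0")
        if self.direction not in ("P3->P2", "P3->P1"):
            raise ValueError("direction must be 'P3->P2' or 'P3->P1'")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    gamma: float | None = None
    direction: str | None = None
    causal_window: int | None = None
    tract_windows: tuple[int, ...] = ()
    planted_sv_index: int | None = None
    planted_sv_folded_freq: float | None = None
    pop_samples: dict[str, list[str]] = field(default_factory=dict)


def _masks_to_matrix(
    masks: np.ndarray,
    pop_names: list[str],
    diploids_per_pop: int,
    outgroup: str,
    positions: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Convert per-site derived-lineage masks to a GenotypeMatrix.

    Monomorphic sites and sites where the outgroup itself is polymorphic
    (ancestral state unresolvable) are dropped.
    """
    n_pops = len(pop_names)
    n_lin = 2 * diploids_per_pop * n_pops
    seg = masks != 0
    out_idx = pop_names.index(outgroup)
    lin_per_pop = 2 * diploids_per_pop
    out_bits_lo = out_idx * lin_per_pop
    out_mask = ((np.int64(1) << lin_per_pop) - 1) << out_bits_lo
    out_derived = masks & out_mask
    poly_out = (out_derived != 0) & (out_derived != out_mask)
    keep = seg & ~poly_out
    kept = masks[keep]
    if positions is None:
        positions = np.arange(len(masks), dtype=np.int64)
    pos = positions[keep]
    # dosage per diploid = popcount of its two lineage bits
    n_dip = diploids_per_pop * n_pops
    geno = np.zeros((len(kept), n_dip), dtype=np.int8)
    for d in range(n_dip):
        b0 = np.int64(1) << (2 * d)
        b1 = np.int64(1) << (2 * d + 1)
        geno[:, d] = ((kept & b0) != 0).astype(np.int8) + ((kept & b1) != 0).astype(np.int8)
    samples: list[str] = []
    pop_samples: dict[str, list[str]] = {}
    for p, name in enumerate(pop_names):
        ids = [f"{name}_{k}" for k in range(diploids_per_pop)]
        pop_samples[name] = ids
        samples.extend(ids)
    gm = GenotypeMatrix(
        chrom=np.asarray([SIM_CHROM] * len(kept), dtype=object),
        pos=pos,
        ref=np.asarray(["A"] * len(kept), dtype=object),
        alt=np.asarray(["T"] * len(kept), dtype=object),
        genotypes=geno,
        samples=samples,
    )
    return gm, pop_samples


def simulate_quartet(params: QuartetSimParams) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate quartet genotypes under (((P1,P2),P3),O) with a pulse."""
    pop_names = ["P1", "P2", "P3", "O"]
    k = 2 * params.samples_per_pop
    lineage_pop = np.repeat(np.arange(4), k)
    recipient = 1 if params.direction == "P3->P2" else 0
    events = []
    if params.gamma > 0:
        events.append((params.t_gf, EV_PULSE, recipient, 2, params.gamma))
    events += [
        (params.t12, EV_MERGE, 0, 1, 0.0),
        (params.t123, EV_MERGE, 0, 2, 0.0),
        (params.t_root, EV_MERGE, 0, 3, 0.0),
    ]
    masks = simulate_site_masks(params.n_sites, lineage_pop, events, params.theta, params.seed)
    gm, pop_samples = _masks_to_matrix(masks, pop_names, params.samples_per_pop, "O")
    truth = SimTruth(gamma=params.gamma, direction=params.direction, pop_samples=pop_samples)
    return gm, truth


def simulate_species_tree_5taxa(
    gamma: float,
    donor: str = "P4",
    t_gf: float = 1.5,
    split_times: tuple[float, float, float, float] = (1.0, 2.0, 3.0, 4.0),
    samples_per_pop: int = 2,
    n_sites: int = 50_000,
    theta: float = 0.01,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """5-taxon tree ((((P1,P2),P3),P4),O) with a pulse from ``donor`` into
    the ancestral branch of (P1,P2) at time ``t_gf`` (t12 < t_gf < t123).

    Exercises the f-branch decomposition: the planted signal should land on
    the internal branch above (P1,P2) in the ``donor`` column.
    """
    t12, t123, t1234, t_root = split_times
    if not (t12 < t_gf < t123):
        raise ValueError("ancestral pulse needs t12 < t_gf < t123")
    pop_names = ["P1", "P2", "P3", "P4", "O"]
    donor_idx = pop_names.index(donor)
    k = 2 * samples_per_pop
    lineage_pop = np.repeat(np.arange(5), k)
    events = [(t12, EV_MERGE, 0, 1, 0.0)]
    if gamma > 0:
        events.append((t_gf, EV_PULSE, 0, donor_idx, gamma))
    events += [
        (t123, EV_MERGE, 0, 2, 0.0),
        (t1234, EV_MERGE, 0, 3, 0.0),
        (t_root, EV_MERGE, 0, 4, 0.0),
    ]
    masks = simulate_site_masks(n_sites, lineage_pop, events, theta, seed)
    gm, pop_samples = _masks_to_matrix(masks, pop_names, samples_per_pop, "O")
    truth = SimTruth(gamma=gamma, direction=f"{donor}->anc(P1,P2)", pop_samples=pop_samples)
    return gm, truth


def simulate_rnd_scenario(
    n_windows: int = 100,
    window_size: int = 10_000,
    tract_windows: tuple[int, ...] = (),
    samples_per_pop: int = 2,
    dxy_background: float = 0.02,
    dxy_outgroup: float = 0.05,
    dxy_tract: float = 0.004,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Two ingroups (X, Y) + outgroup O with an introgressed tract.

    Per callable site a mutation falls on the X branch, Y branch, the
    internal (X,Y) branch, or the O branch, with rates chosen so that
    E[d_XY] equals ``dxy_background`` off-tract and ``dxy_tract`` on-tract
    while E[d_XO] and E[d_YO] are ``dxy_outgroup`` everywhere (recent
    introgression shortens only the X-Y coalescence time). Variants are
    fixed within populations; every base of every window is callable.
    """
    for t in tract_windows:
        if not 0 <= t < n_windows:
            raise ValueError(f"tract window {t} outside [0, {n_windows})")
    if not dxy_tract <= dxy_background < dxy_outgroup:
        raise ValueError("need dxy_tract <= dxy_background < dxy_outgroup")
    rng = np.random.default_rng(seed)
    samples: list[str] = []
    for name in ("X", "Y", "O"):
        samples.extend(f"{name}_{k}" for k in range(samples_per_pop))
    n_per = samples_per_pop
    tract = set(tract_windows)

    chroms: list[str] = []
    pos_all: list[np.ndarray] = []
    genos: list[np.ndarray] = []
    callable_sites: dict[tuple[str, int, int], int] = {}
    for w in range(n_windows):
        d_xy = dxy_tract if w in tract else dxy_background
        # rates per category; the internal (X,Y) branch absorbs exactly what
        # the X/Y tip branches lose on-tract, so E[dXO] = E[dYO] =
        # p_tip + p_int + p_o = dxy_outgroup both on- and off-tract
        p_x = p_y = d_xy / 2.0
        p_o = dxy_outgroup / 2.0
        p_int = dxy_outgroup / 2.0 - d_xy / 2.0
        probs = np.array([p_x, p_y, p_int, p_o])
        counts = rng.multinomial(window_size, np.append(probs, 1.0 - probs.sum()))[:4]
        n_var = int(counts.sum())
        start = w * window_size
        callable_sites[(SIM_CHROM, start, start + window_size)] = window_size
        if n_var == 0:
            continue
        p = np.sort(rng.choice(window_size, size=n_var, replace=False)) + start
        cat = np.repeat(np.arange(4), counts)
        rng.shuffle(cat)
        # order positions ascending with shuffled categories
        g = np.zeros((n_var, 3 * n_per), dtype=np.int8)
        g[cat == 0, 0:n_per] = 2  # X-private
        g[cat == 1, n_per : 2 * n_per] = 2  # Y-private
        g[cat == 2, 0 : 2 * n_per] = 2  # shared X+Y (internal branch)
        g[cat == 3, 2 * n_per : 3 * n_per] = 2  # O branch
        pos_all.append(p)
        genos.append(g)
    pos = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
    geno = np.vstack(genos) if genos else np.empty((0, 3 * n_per), dtype=np.int8)
    gm = GenotypeMatrix(
        chrom=np.asarray([SIM_CHROM] * len(pos), dtype=object),
        pos=pos.astype(np.int64),
        ref=np.asarray(["A"] * len(pos), dtype=object),
        alt=np.asarray(["T"] * len(pos), dtype=object),
        genotypes=geno,
        samples=samples,
        callable_sites=callable_sites,
    )
    truth = SimTruth(
        tract_windows=tuple(sorted(tract)),
        pop_samples={
            "X": samples[:n_per],
            "Y": samples[n_per : 2 * n_per],
            "O": samples[2 * n_per :],
        },
    )
    return gm, truth


def simulate_coverage(
    n_species: int = 21,
    n_windows: int = 1000,
    morphs: list[Morph] | None = None,
    background_presence: float = 0.98,
    causal_index: int | None = 0,
    flip_noise: float = 0.0,
    window_size: int = 600,
    seed: int = 0,
) -> tuple[CoverageMatrix, SimTruth]:
    """Binary coverage matrix with one morph-segregating window.

    Non-causal cells are Bernoulli(``background_presence``); in the causal
    window presence equals (morph == alba), then flips with probability
    ``flip_noise``.
    """
    if morphs is None:
        # roughly balanced morph assignment across species
        morphs = [Morph.alba if i % 2 == 0 else Morph.colored for i in range(n_species)]
    if len(morphs) != n_species:
        raise ValueError("need one morph per species")
    alba = np.asarray([m == Morph.alba for m in morphs])
    if not alba.any() or not (~alba).any():
        raise ValueError("coverage statistic needs both alba and colored species")
    if causal_index is not None and not 0 <= causal_index < n_windows:
        raise ValueError("causal_index outside window range")
    rng = np.random.default_rng(seed)
    presence = rng.random((n_species, n_windows)) < background_presence
    if causal_index is not None:
        col = alba.copy()
        flips = rng.random(n_species) < flip_noise
        presence[:, causal_index] = col ^ flips
    windows = [
        WindowSpec(SIM_CHROM, w * window_size, (w + 1) * window_size)
        for w in range(n_windows)
    ]
    species = [f"species_{i}" for i in range(n_species)]
    matrix = CoverageMatrix(windows, species, list(morphs), presence)
    truth = SimTruth(causal_window=causal_index)
    return matrix, truth


def coverage_sample_sheet(matrix: CoverageMatrix) -> SampleSheet:
    """One-sample-per-species sheet matching a simulated coverage matrix."""
    return SampleSheet(
        SampleInfo(sample_id=f"{sp}_s0", species=sp, morph=m)
        for sp, m in zip(matrix.species, matrix.morphs)
    )


def coverage_to_tracks(matrix: CoverageMatrix, depth: float = 30.0):
    """BedGraph-style depth tracks realising a coverage matrix exactly."""
    from .core import DepthTrack

    tracks = []
    for i, sp in enumerate(matrix.species):
        chrom, start, end, dep = [], [], [], []
        for j, w in enumerate(matrix.windows):
            chrom.append(w.chrom)
            start.append(w.start)
            end.append(w.end)
            dep.append(depth if matrix.presence[i, j] else 0.0)
        tracks.append(
            DepthTrack(
                sample_id=f"{sp}_s0",
                chrom=np.asarray(chrom, dtype=object),
                start=np.asarray(start),
                end=np.asarray(end),
                depth=np.asarray(dep),
            )
        )
    return tracks


def simulate_sv_table(
    n_sv: int = 1000,
    n_samples: int = 29,
    planted_freq: float | None = 0.47,
    seed: int = 0,
) -> tuple[SVTable, SimTruth]:
    """Indel table with a neutral folded spectrum plus one planted record.

    Neutral records draw a minor-allele count i from the folded neutral
    spectrum (probability proportional to 1/i + 1/(2n-i)) and genotypes
    Hardy-Weinberg at that frequency. The planted record carries exactly
    ``round(planted_freq * 2n)`` minor alleles.
    """
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    if planted_freq is not None and not 0.0 < planted_freq <= 0.5:
        raise ValueError("planted frequency must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    two_n = 2 * n_samples
    minor = np.arange(1, two_n // 2 + 1)
    weights = 1.0 / minor + 1.0 / (two_n - minor)
    weights /= weights.sum()
    n_neutral = n_sv - (1 if planted_freq is not None else 0)
    if n_neutral < 0:
        raise ValueError("n_sv must be >= 1")
    freqs = minor[rng.choice(len(minor), size=n_neutral, p=weights)] / two_n
    geno = rng.binomial(2, freqs[:, None], size=(n_neutral, n_samples)).astype(np.int8)
    planted_index: int | None = None
    if planted_freq is not None:
        count = int(round(planted_freq * two_n))
        row = np.zeros(n_samples, dtype=np.int8)
        row[: count // 2] = 2
        if count % 2:
            row[count // 2] = 1
        planted_index = int(rng.integers(0, n_neutral + 1)) if n_neutral else 0
        geno = np.insert(geno, planted_index, row, axis=0)
    n_total = geno.shape[0]
    sv_type = np.asarray(
        [SVType.INS if b else SVType.DEL for b in rng.random(n_total) < 0.5],
        dtype=object,
    )
    table = SVTable(
        chrom=np.asarray([SIM_CHROM] * n_total, dtype=object),
        pos=np.arange(1, n_total + 1, dtype=np.int64) * 1000,
        sv_type=sv_type,
        length=rng.integers(50, 5000, size=n_total).astype(np.int64),
        filter_pass=np.ones(n_total, dtype=bool),
        genotypes=geno,
        gq=np.full((n_total, n_samples), 99.0),
        samples=[f"ce_{k}" for k in range(n_samples)],
    )
    truth = SimTruth(
        planted_sv_index=planted_index,
        planted_sv_folded_freq=(
            min(planted_freq, 1.0 - planted_freq) if planted_freq is not None else None
        ),
    )
    return table, truth


def quartet_sample_sheet(
    truth: SimTruth,
    morphs: dict[str, Morph] | None = None,
) -> SampleSheet:
    """Sample sheet for a simulated quartet/5-taxon dataset."""
    morphs = morphs or {}
    infos = []
    for pop, ids in truth.pop_samples.items():
        for sid in ids:
            infos.append(
                SampleInfo(sample_id=sid, species=pop, morph=morphs.get(pop, Morph.unknown))
            )
    return SampleSheet(infos)
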