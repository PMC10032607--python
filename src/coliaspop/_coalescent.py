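"""Per-site coalescent kernel for the synthetic-data generators.

Sites are simulated independently (no recombination structure): for each
site a genealogy of the sampled lineages is drawn under a multi-population
coalescent with a merge schedule (the species tree) and an optional
admixture pulse, mutations fall as Poisson(theta * tree length), and an
infinite-sites site is collapsed to a single biallelic mutation placed
uniformly by branch length. Lineage sets are tracked as 64-bit masks, so at
most 64 haploid lineages are supported.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event types
EV_PULSE = 0  # move all lineages of pop a to pop b with per-site prob gamma
EV_MERGE = 1  # relabel pop b lineages as pop a


@njit(cache=True)
def _simulate_site_masks(
    n_sites: int,
    lineage_pop0: np.ndarray,  # int64[n_lin] initial population of each lineage
    event_times: np.ndarray,  # float64[n_events], non-decreasing
    event_types: np.ndarray,  # int64[n_events]
    event_a: np.ndarray,  # int64[n_events]
    event_b: np.ndarray,  # int64[n_events]
    event_gamma: np.ndarray,  # float64[n_events]
    theta: float,
    seed: int,
) -> np.ndarray:
    np.random.seed(seed)
    n_lin = lineage_pop0.shape[0]
    n_events = event_times.shape[0]
    out = np.zeros(n_sites, dtype=np.int64)

    lin_mask = np.zeros(n_lin, dtype=np.int64)
    lin_pop = np.zeros(n_lin, dtype=np.int64)
    lin_birth = np.zeros(n_lin, dtype=np.float64)
    br_mask = np.zeros(2 * n_lin, dtype=np.int64)
    br_len = np.zeros(2 * n_lin, dtype=np.float64)

    for s in range(n_sites):
        for i in range(n_lin):
            lin_mask[i] = np.int64(1) << i
            lin_pop[i] = lineage_pop0[i]
            lin_birth[i] = 0.0
        m = n_lin
        nb = 0
        t = 0.0
        ev = 0
        while m > 1:
            # coalescence rate summed over populations
            rate = 0.0
            for p in range(8):
                k = 0
                for i in range(m):
                    if lin_pop[i] == p:
                        k += 1
                rate += k * (k - 1) / 2.0
            t_event = event_times[ev] if ev < n_events else np.inf
            if rate > 0.0:
                dt = np.random.exponential(1.0 / rate)
            else:
                dt = np.inf
            if t + dt >= t_event:
                # apply the demographic event
                t = t_event
                a = event_a[ev]
                b = event_b[ev]
                if event_types[ev] == EV_PULSE:
                    if np.random.random() < event_gamma[ev]:
                        for i in range(m):
                            if lin_pop[i] == a:
                                lin_pop[i] = b
                else:
                    for i in range(m):
                        if lin_pop[i] == b:
                            lin_pop[i] = a
                ev += 1
                continue
            t += dt
            # choose population proportional to its pair count
            u = np.random.random() * rate
            acc = 0.0
            chosen = -1
            for p in range(8):
                k = 0
                for i in range(m):
                    if lin_pop[i] == p:
                        k += 1
                acc += k * (k - 1) / 2.0
                if u < acc:
                    chosen = p
                    break
            # choose an unordered pair within the chosen population
            k = 0
            for i in range(m):
                if lin_pop[i] == chosen:
                    k += 1
            r1 = np.random.randint(0, k)
            r2 = np.random.randint(0, k - 1)
            if r2 >= r1:
                r2 += 1
            i1 = -1
            i2 = -1
            c = 0
            for i in range(m):
                if lin_pop[i] == chosen:
                    if c == r1:
                        i1 = i
                    if c == r2:
                        i2 = i
                    c += 1
            # record the two child branches
            br_mask[nb] = lin_mask[i1]
            br_len[nb] = t - lin_birth[i1]
            nb += 1
            br_mask[nb] = lin_mask[i2]
            br_len[nb] = t - lin_birth[i2]
            nb += 1
            lin_mask[i1] = lin_mask[i1] | lin_mask[i2]
            lin_birth[i1] = t
            # swap-remove i2
            lin_mask[i2] = lin_mask[m - 1]
            lin_pop[i2] = lin_pop[m - 1]
            lin_birth[i2] = lin_birth[m - 1]
            m -= 1
        total_len = 0.0
        for j in range(nb):
            total_len += br_len[j]
        # infinite sites collapsed to biallelic: segregate iff >=1 mutation,
        # the mutated branch drawn uniformly by length
        if np.random.random() < 1.0 - np.exp(-theta * total_len):
            u = np.random.random() * total_len
            acc = 0.0
            for j in range(nb):
                acc += br_len[j]
                if u < acc:
                    out[s] = br_mask[j]
                    break
    return out


def simulate_site_masks(
    n_sites: int,
    lineage_pop: np.ndarray,
    events: list[tuple[float, int, int, int, float]],
    theta: float,
    seed: int,
) -> np.ndarray:
    """Derived-lineage bitmask per site (0 = monomorphic).

    ``events`` is a time-sorted list of (time, type, pop_a, pop_b, gamma)
    tuples with type EV_PULSE or EV_MERGE.
    """
    lineage_pop = np.asarray(lineage_pop, dtype=np.int64)
    if lineage_pop.max(initial=0) > 7:
        raise ValueError("at most 8 populations supported")
    if len(lineage_pop) > 64:
        raise ValueError("at most 64 haploid lineages supported")
    ts = np.asarray([e[0] for e in events], dtype=np.float64)
    if (np.diff(ts) < 0).any():
        raise ValueError("events must be time-sorted")
    return _simulate_site_masks(
        int(n_sites),
        lineage_pop,
        ts,
        np.asarray([e[1] for e in events], dtype=np.int64),
        np.asarray([e[2] for e in events], dtype=np.int64),
        np.asarray([e[3] for e in events], dtype=np.int64),
        np.asarray([e[4] for e in events], dtype=np.float64),
        float(theta),
        int(seed) % (2**32 - 1),
    )
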