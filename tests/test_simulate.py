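"""Synthetic-data generator calibration and determinism."""

import numpy as np
import pytest

from coliaspop import introgression as ig
from coliaspop.simulate import (
    QuartetSimParams,
    simulate_coverage,
    simulate_quartet,
    simulate_rnd_scenario,
    simulate_sv_table,
)


def quartet_d(gamma, n_sites, seed, **kw):
    gm, truth = simulate_quartet(
        QuartetSimParams(gamma=gamma, n_sites=n_sites, seed=seed, **kw)
    )
    ps = truth.pop_samples
    s = ig.site_pattern_sums(gm, ps["P1"], ps["P2"], ps["P3"], ps["O"])
    return ig.patterson_d(s)


class TestQuartet:
    def test_seed_determinism(self):
        a, _ = simulate_quartet(QuartetSimParams(n_sites=3000, gamma=0.4, seed=42))
        b, _ = simulate_quartet(QuartetSimParams(n_sites=3000, gamma=0.4, seed=42))
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.pos, b.pos)

    def test_different_seeds_differ(self):
        a, _ = simulate_quartet(QuartetSimParams(n_sites=3000, seed=1))
        b, _ = simulate_quartet(QuartetSimParams(n_sites=3000, seed=2))
        assert a.n_sites != b.n_sites or not np.array_equal(a.genotypes, b.genotypes)

    def test_invalid_times_error(self):
        with pytest.raises(ValueError):
            QuartetSimParams(t_gf=2.0, t12=1.0)

    def test_null_mean_d_within_monte_carlo_error(self):
        # modest replicate count here; the full 500-replicate check runs in
        # the acceptance suite
        ds = [quartet_d(0.0, 20_000, seed) for seed in range(40)]
        ds = np.asarray(ds, dtype=float)
        se = ds.std(ddof=1) / np.sqrt(len(ds))
        assert abs(ds.mean()) < 3 * se

    def test_complete_replacement_drives_d_to_one(self):
        # gamma = 1 with immediate pulse: P2 is a P3 lineage sample; with a
        # long internal branch D approaches its upper bound
        d = quartet_d(1.0, 30_000, 3, t_gf=0.01, t123=3.0, t_root=4.0, t12=1.0)
        assert d > 0.9

    def test_full_pulse_makes_p2_p3_frequencies_exchangeable(self):
        gm, truth = simulate_quartet(
            QuartetSimParams(gamma=1.0, t_gf=0.01, n_sites=30_000, seed=4)
        )
        ps = truth.pop_samples
        f2 = gm.alt_freqs(ps["P2"])
        f3 = gm.alt_freqs(ps["P3"])
        # P2 and P3 frequencies identically distributed: matched moments
        assert f2.mean() == pytest.approx(f3.mean(), abs=0.02)
        assert np.corrcoef(f2, f3)[0, 1] > 0.5

    def test_msprime_oracle_for_pulse_f4_ratio(self):
        """Cross-check the f4-ratio under an admixture pulse against msprime.

        The generator relocates the whole recipient lineage set per site
        (sites are wholly introgressed or not) while msprime moves lineages
        independently; the f4-ratio has the same expectation under both
        pulse models, so it is the right quantity to compare.
        """
        import msprime

        params = QuartetSimParams(gamma=0.3, n_sites=120_000, seed=11)
        gm, truth = simulate_quartet(params)
        ps = truth.pop_samples
        f_ours = ig.f4_ratio(gm, ps["P1"], ps["P2"], ps["P3"], ps["O"])

        demography = msprime.Demography()
        for name in ("P1", "P2", "P3", "O", "anc12", "anc123", "root"):
            demography.add_population(name=name, initial_size=0.5)
        # coalescent-unit times (2N gen with N = 0.5 diploids => time unit 1)
        demography.add_admixture(
            time=params.t_gf, derived="P2", ancestral=["P3", "anc12"],
            proportions=[params.gamma, 1 - params.gamma],
        )
        demography.add_population_split(
            time=params.t12, derived=["P1"], ancestral="anc12"
        )
        demography.add_population_split(
            time=params.t123, derived=["anc12", "P3"], ancestral="anc123"
        )
        demography.add_population_split(
            time=params.t_root, derived=["anc123", "O"], ancestral="root"
        )
        num = den = 0.0
        reps = msprime.sim_ancestry(
            samples={"P1": 2, "P2": 2, "P3": 2, "O": 2},
            demography=demography,
            sequence_length=1,
            num_replicates=40_000,
            random_seed=7,
        )
        for i, ts in enumerate(reps):
            mts = msprime.sim_mutations(ts, rate=0.01, random_seed=1000 + i)
            for var in mts.variants():
                g = np.asarray(var.genotypes)
                if len(var.alleles) != 2:
                    continue
                p1, p2, p3, p4 = (g[k * 4 : (k + 1) * 4].mean() for k in range(4))
                c3 = int(g[8:12].sum())
                if p4 == 0.5:
                    continue
                if p4 > 0.5:
                    p1, p2, p3, p4 = 1 - p1, 1 - p2, 1 - p3, 1 - p4
                    c3 = 4 - c3
                num += (1 - p1) * p2 * p3 * (1 - p4) - p1 * (1 - p2) * p3 * (1 - p4)
                p3sq = c3 * (c3 - 1) / 12.0
                p3q3 = c3 * (4 - c3) / 12.0
                den += (1 - p1) * p3sq * (1 - p4) - p1 * p3q3 * (1 - p4)
        f_msprime = num / den
        assert f_ours == pytest.approx(f_msprime, abs=0.05)


class TestRndScenario:
    def test_null_run_lower_tail_rate_is_five_percent(self):
        from coliaspop import divergence as dv
        from coliaspop.core import WindowSpec

        gm, truth = simulate_rnd_scenario(n_windows=200, tract_windows=(), seed=5)
        assert truth.tract_windows == ()
        windows = [WindowSpec(c, s, e) for (c, s, e) in gm.callable_sites]
        ps = truth.pop_samples
        series = [
            dv.dxy_windows(gm, ps[a], ps[b], windows)
            for a, b in (("X", "Y"), ("X", "O"), ("Y", "O"))
        ]
        rnd = dv.rnd_windows(*series)
        values = [r.rnd for r in rnd]
        thr = dv.quantile_threshold(values, 0.05)
        rate = np.mean([v <= thr for v in values])
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_seed_determinism(self):
        a, _ = simulate_rnd_scenario(n_windows=30, tract_windows=(3,), seed=6)
        b, _ = simulate_rnd_scenario(n_windows=30, tract_windows=(3,), seed=6)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)

    def test_bad_tract_index_errors(self):
        with pytest.raises(ValueError):
            simulate_rnd_scenario(n_windows=10, tract_windows=(10,))


class TestCoverageSim:
    def test_noise_free_causal_window_statistic_is_one(self):
        from coliaspop.coverage import color_bias_scan

        matrix, truth = simulate_coverage(n_windows=20, causal_index=4, seed=7)
        assert color_bias_scan(matrix)[truth.causal_window].bias == 1.0

    def test_saturated_background_no_causal_all_zero(self):
        from coliaspop.coverage import color_bias_scan

        matrix, _ = simulate_coverage(
            n_windows=15, background_presence=1.0, causal_index=None, seed=8
        )
        assert all(s.bias == 0.0 for s in color_bias_scan(matrix))

    def test_single_morph_errors(self):
        from coliaspop.core import Morph

        with pytest.raises(ValueError):
            simulate_coverage(n_species=3, morphs=[Morph.alba] * 3)


class TestSvSim:
    def test_single_record(self):
        table, _ = simulate_sv_table(n_sv=1, n_samples=10, planted_freq=0.3, seed=9)
        assert table.n_records == 1

    def test_folded_frequencies_bounded(self):
        from coliaspop.balancing import folded_afs

        table, _ = simulate_sv_table(n_sv=2000, n_samples=15, seed=10)
        assert (folded_afs(table) <= 0.5).all()

    def test_planted_record_has_requested_frequency(self):
        from coliaspop.balancing import folded_afs

        table, truth = simulate_sv_table(n_sv=500, n_samples=29, planted_freq=0.47, seed=11)
        afs = folded_afs(table)
        assert afs[truth.planted_sv_index] == pytest.approx(
            round(0.47 * 58) / 58, abs=1e-12
        )

    def test_seed_determinism(self):
        a, _ = simulate_sv_table(n_sv=100, seed=12)
        b, _ = simulate_sv_table(n_sv=100, seed=12)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
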