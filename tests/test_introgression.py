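"""Unit and oracle tests for the ABBA-BABA machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats

from coliaspop import introgression as ig
from coliaspop.core import Morph, MorphGroup, SampleInfo, SampleSheet
from coliaspop.simulate import QuartetSimParams, simulate_quartet
from coliaspop.tree import SpeciesTree
from conftest import make_matrix, random_matrix

POPS = (["s0", "s1"], ["s2", "s3"], ["s4", "s5"], ["s6", "s7"])


def brute_force_pattern_sums(gm, pops):
    """Per-site python-loop oracle for ABBA/BABA totals."""
    abba = baba = 0.0
    for i in range(gm.n_sites):
        freqs = []
        for pop in pops:
            idx = [gm.samples.index(s) for s in pop]
            calls = [gm.genotypes[i, j] for j in idx if gm.genotypes[i, j] != -1]
            if not calls:
                freqs = None
                break
            freqs.append(sum(calls) / (2 * len(calls)))
        if freqs is None or freqs[3] == 0.5:
            continue
        if freqs[3] > 0.5:
            freqs = [1 - f for f in freqs]
        p1, p2, p3, p4 = freqs
        abba += (1 - p1) * p2 * p3 * (1 - p4)
        baba += p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


class TestSitePatternSums:
    def test_pure_abba_site(self):
        gm = make_matrix([[0, 0, 2, 2, 2, 2, 0, 0]])
        s = ig.site_pattern_sums(gm, *POPS, n_blocks=1)
        assert (s.total_abba, s.total_baba) == (1.0, 0.0)

    def test_pure_baba_site(self):
        gm = make_matrix([[2, 2, 0, 0, 2, 2, 0, 0]])
        s = ig.site_pattern_sums(gm, *POPS, n_blocks=1)
        assert (s.total_abba, s.total_baba) == (0.0, 1.0)

    def test_matches_brute_force_oracle(self, rng):
        gm = random_matrix(rng, n_sites=200)
        s = ig.site_pattern_sums(gm, *POPS, n_blocks=7)
        abba, baba = brute_force_pattern_sums(gm, POPS)
        assert s.total_abba == pytest.approx(abba, abs=1e-12)
        assert s.total_baba == pytest.approx(baba, abs=1e-12)

    def test_empty_population_errors(self, rng):
        gm = random_matrix(rng, n_sites=50)
        with pytest.raises(ValueError):
            ig.site_pattern_sums(gm, [], POPS[1], POPS[2], POPS[3])


class TestPattersonD:
    @pytest.mark.parametrize(
        "abba,baba,expected", [(12.5, 12.5, 0.0), (1.0, 0.0, 1.0), (0.0, 3.0, -1.0)]
    )
    def test_arithmetic(self, abba, baba, expected):
        s = ig.SitePatternSums(
            np.asarray([abba]), np.asarray([baba]), np.asarray([0, 1])
        )
        assert ig.patterson_d(s) == pytest.approx(expected)

    def test_zero_denominator_flagged(self):
        s = ig.SitePatternSums(np.zeros(2), np.zeros(2), np.asarray([0, 1, 2]))
        assert ig.patterson_d(s) is None


def busing_jackknife_oracle(abba, baba):
    """Independent scalar-loop weighted delete-one jackknife."""
    w = [a + b for a, b in zip(abba, baba)]
    keep = [j for j in range(len(w)) if w[j] > 0]
    abba = [abba[j] for j in keep]
    baba = [baba[j] for j in keep]
    w = [w[j] for j in keep]
    g = len(w)
    n = sum(w)
    d = (sum(abba) - sum(baba)) / n
    d_del = []
    for j in range(g):
        num = sum(a for k, a in enumerate(abba) if k != j) - sum(
            b for k, b in enumerate(baba) if k != j
        )
        d_del.append(num / (n - w[j]))
    theta_j = g * d - sum((1 - w[j] / n) * d_del[j] for j in range(g))
    var = 0.0
    for j in range(g):
        h = n / w[j]
        tau = h * d - (h - 1) * d_del[j]
        var += (tau - theta_j) ** 2 / (h - 1)
    var /= g
    se = var**0.5
    z = d / se
    return z, 2 * stats.norm.sf(abs(z))


class TestJackknife:
    def test_matches_naive_loop_oracle(self, rng):
        abba = rng.gamma(5.0, 2.0, size=20)
        baba = rng.gamma(4.0, 2.0, size=20)
        s = ig.SitePatternSums(abba, baba, np.arange(21))
        z, p = ig.jackknife_significance(s)
        z0, p0 = busing_jackknife_oracle(abba.tolist(), baba.tolist())
        assert z == pytest.approx(z0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    def test_degenerate_se_zero_flagged(self):
        # identical blocks: every delete-one estimate equals D
        abba = np.full(5, 3.0)
        baba = np.full(5, 1.0)
        s = ig.SitePatternSums(abba, baba, np.arange(6))
        assert ig.jackknife_significance(s) == (None, None)

    def test_too_few_blocks_flagged(self):
        s = ig.SitePatternSums(
            np.asarray([1.0, 2.0]), np.asarray([0.5, 0.1]), np.arange(3)
        )
        assert ig.jackknife_significance(s) == (None, None)


class TestHolm:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            ig.holm_correct([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        assert ig.holm_correct([0.2]).tolist() == [0.2]

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            expected = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(ig.holm_correct(p), expected, atol=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            ig.holm_correct([0.5, 1.5])


class TestEnumerateTrios:
    @pytest.fixture
    def five_species_data(self, rng):
        n_per = 2
        species = [f"sp{i}" for i in range(5)] + ["out"]
        infos = [
            SampleInfo(f"{sp}_{k}", sp, morph=Morph.colored)
            for sp in species
            for k in range(n_per)
        ]
        sheet = SampleSheet(infos)
        g = rng.integers(0, 3, size=(400, len(infos))).astype(np.int8)
        gm = make_matrix(g, samples=[s.sample_id for s in infos])
        return gm, sheet

    def test_trio_count_is_n_choose_3(self, five_species_data):
        gm, sheet = five_species_data
        results = ig.enumerate_trios(gm, sheet, "out")
        assert len(results) == 10

    def test_dmin_nonnegative_and_holm_ge_raw(self, five_species_data):
        gm, sheet = five_species_data
        for r in ig.enumerate_trios(gm, sheet, "out"):
            assert r.dmin is None or r.dmin >= 0
            if r.p_holm is not None:
                assert r.p_holm >= r.p_raw

    def test_planted_gene_flow_appears_in_p2_p3(self):
        gm, truth = simulate_quartet(
            QuartetSimParams(gamma=0.6, n_sites=50_000, seed=21)
        )
        infos = [
            SampleInfo(sid, sp, morph=Morph.colored)
            for sp, ids in truth.pop_samples.items()
            for sid in ids
        ]
        sheet = SampleSheet(infos)
        [r] = ig.enumerate_trios(gm, sheet, "O", species=["P1", "P2", "P3"])
        # flow was P3 -> P2: the donor pair must sit in (P2, P3)
        assert {r.p2, r.p3} == {"P2", "P3"}
        assert r.dmin > 0

    def test_missing_species_errors(self, five_species_data):
        gm, sheet = five_species_data
        with pytest.raises(ValueError):
            ig.enumerate_trios(gm, sheet, "out", species=["sp0", "sp1", "ghost"])


class TestF4Ratio:
    def test_full_introgression_recovers_one(self):
        # gamma=1 with an immediate pulse makes P2 a copy of P3
        gm, truth = simulate_quartet(
            QuartetSimParams(gamma=1.0, t_gf=0.01, n_sites=30_000, seed=5)
        )
        ps = truth.pop_samples
        f = ig.f4_ratio(gm, ps["P1"], ps["P2"], ps["P3"], ps["O"])
        assert f == pytest.approx(1.0, abs=0.05)

    def test_no_introgression_near_zero(self):
        gm, truth = simulate_quartet(QuartetSimParams(gamma=0.0, n_sites=50_000, seed=6))
        ps = truth.pop_samples
        f = ig.f4_ratio(gm, ps["P1"], ps["P2"], ps["P3"], ps["O"])
        assert f == pytest.approx(0.0, abs=0.03)


class TestFBranch:
    def test_reduction_to_f4_ratio_on_four_taxon_tree(self):
        gm, truth = simulate_quartet(QuartetSimParams(gamma=0.3, n_sites=20_000, seed=7))
        ps = truth.pop_samples
        tree = SpeciesTree.from_newick("(((P1,P2),P3),O);")
        fb = ig.f_branch(tree, gm, ps, "O")
        # terminal branch P2 with donor P3 has the single proxy P1
        expected = ig.f4_ratio(gm, ps["P1"], ps["P2"], ps["P3"], ps["O"])
        assert fb.cell("P2", "P3") == pytest.approx(expected, abs=1e-12)

    def test_internal_branch_cells_inadmissible_on_four_taxon_tree(self):
        gm, truth = simulate_quartet(QuartetSimParams(gamma=0.0, n_sites=5_000, seed=8))
        tree = SpeciesTree.from_newick("(((P1,P2),P3),O);")
        fb = ig.f_branch(tree, gm, truth.pop_samples, "O")
        idx = [b.label for b in fb.branches].index("anc_1(P1,P2)")
        assert np.isnan(fb.values[idx]).all()

    def test_null_simulation_cells_near_zero(self):
        from coliaspop.simulate import simulate_species_tree_5taxa

        gm, truth = simulate_species_tree_5taxa(gamma=0.0, n_sites=50_000, seed=9)
        tree = SpeciesTree.from_newick("((((P1,P2),P3),P4),O);")
        fb = ig.f_branch(tree, gm, truth.pop_samples, "O")
        finite = fb.values[np.isfinite(fb.values) & (fb.values > -0.2)]
        assert np.abs(finite).max() < 0.1

    def test_clamped_view_nonnegative(self, rng):
        gm = random_matrix(rng, n_sites=300)
        tree = SpeciesTree.from_newick("(((P1,P2),P3),O);")
        pops = {"P1": ["s0", "s1"], "P2": ["s2", "s3"], "P3": ["s4", "s5"], "O": ["s6", "s7"]}
        fb = ig.f_branch(tree, gm, pops, "O")
        v = fb.clamped()
        assert (v[np.isfinite(v)] >= 0).all()


class TestWindowScan:
    def test_symmetric_frequencies_give_zero(self):
        # p1 == p2 at every site -> ABBA == BABA exactly, denominators > 0
        rows = [[0, 1, 0, 1, 2, 2, 0, 0]] * 600
        gm = make_matrix(rows)
        scan = ig.window_scan(gm, *POPS, snps_per_window=500)
        assert scan["f_dM"][0].value == pytest.approx(0.0, abs=1e-12)
        assert scan["d_f"][0].value == pytest.approx(0.0, abs=1e-12)

    def test_fewer_snps_than_window_returns_empty(self, rng):
        gm = random_matrix(rng, n_sites=100)
        scan = ig.window_scan(gm, *POPS, snps_per_window=500)
        assert scan["d_f"] == [] and scan["f_dM"] == []

    def test_planted_tract_windows_are_outliers(self):
        # one chromosome simulated null, one with strong flow; the scan is
        # run over the concatenation and tract windows must top the 95th pct
        gm_null, truth = simulate_quartet(
            QuartetSimParams(gamma=0.0, n_sites=120_000, seed=10)
        )
        gm_flow, _ = simulate_quartet(
            QuartetSimParams(gamma=0.8, n_sites=12_000, seed=11)
        )
        gm_flow.chrom = gm_null.chrom[: gm_flow.n_sites].copy()
        gm_flow.pos = gm_flow.pos + int(gm_null.pos.max()) + 1
        import numpy as np

        merged = make_matrix(
            np.vstack([gm_null.genotypes, gm_flow.genotypes]),
            samples=gm_null.samples,
            pos=np.concatenate([gm_null.pos, gm_flow.pos]),
        )
        ps = truth.pop_samples
        scan = ig.window_scan(merged, ps["P1"], ps["P2"], ps["P3"], ps["O"])
        values = [w.value for w in scan["d_f"] if w.defined]
        threshold = np.percentile(values, 95)
        tract_start = int(gm_null.pos.max()) + 1
        tract_vals = [
            w.value
            for w in scan["d_f"]
            if w.defined and w.window.end > tract_start
        ]
        assert tract_vals and np.mean(tract_vals) > threshold


class TestMorphGroup:
    def _sheet(self, m2, m3):
        return SampleSheet(
            [
                SampleInfo("a", "A", morph=Morph.colored),
                SampleInfo("b", "B", morph=m2),
                SampleInfo("c", "C", morph=m3),
                SampleInfo("o", "O", morph=Morph.colored),
            ]
        )

    def _trio(self):
        return ig.TrioResult("A", "B", "C", "O", {}, 0.1, None, None)

    @pytest.mark.parametrize(
        "m2,m3,expected",
        [
            (Morph.alba, Morph.alba, MorphGroup.AlbaAlba),
            (Morph.colored, Morph.alba, MorphGroup.AlbaColored),
            (Morph.alba, Morph.colored, MorphGroup.AlbaColored),
            (Morph.colored, Morph.colored, MorphGroup.ColoredColored),
            (Morph.alba, Morph.unknown, MorphGroup.undefined),
        ],
    )
    def test_grouping(self, m2, m3, expected):
        assert ig.trio_morph_group(self._trio(), self._sheet(m2, m3)) is expected


def pearson_chi2_oracle(table):
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestEnrichment:
    def test_chi2_matches_hand_oracle(self):
        table = [[30, 70], [10, 90], [10, 90]]
        chi2, df, p = ig.chisq_homogeneity(table)
        assert chi2 == pytest.approx(pearson_chi2_oracle(table), abs=1e-12)
        assert df == 2
        assert p == pytest.approx(np.exp(-chi2 / 2), rel=1e-12)

    def test_published_significant_trio_proportions_accepted(self):
        # significant / non-significant trio counts per morph group
        table = [[447, 866 - 447], [464, 653 - 464], [102, 246 - 102]]
        chi2, df, p = ig.chisq_homogeneity(table)
        assert chi2 == pytest.approx(pearson_chi2_oracle(table), rel=1e-12)
        assert df == 2 and 0 <= p <= 1

    def test_homogeneous_groups_give_zero(self):
        chi2, _, p = ig.chisq_homogeneity([[10, 90], [20, 180], [5, 45]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(25):
            table = rng.integers(1, 200, size=(3, 2))
            chi2, df, _ = ig.chisq_homogeneity(table)
            assert chi2 == pytest.approx(pearson_chi2_oracle(table), rel=1e-10)

    def test_outlier_cross_tabulation(self, rng):
        from coliaspop.core import WindowSpec, WindowStat

        def scanset(values, locus_val):
            wins = [
                WindowStat(WindowSpec("c1", i * 10, i * 10 + 10), "d_f", v)
                for i, v in enumerate(values)
            ]
            wins.append(WindowStat(WindowSpec("c1", 900, 910), "d_f", locus_val))
            return wins

        base = list(rng.random(50) * 0.1)
        scans = {
            "t1": scanset(base, 0.9),   # clear outlier at the locus
            "t2": scanset(base, 0.0),   # not an outlier
            "t3": scanset(base, 0.95),
        }
        groups = {
            "t1": MorphGroup.AlbaAlba,
            "t2": MorphGroup.ColoredColored,
            "t3": MorphGroup.AlbaAlba,
        }
        res = ig.alba_outlier_enrichment(scans, groups, ("c1", 900, 910))
        assert res.table.sum() == 3
        assert res.df == 1  # one empty group dropped
        aa = res.groups.index(MorphGroup.AlbaAlba)
        assert res.table[aa, 0] == 2


class TestChisqSf:
    def test_printed_statistic_reproduces_printed_p(self):
        assert ig.chisq_sf(14.223, 2) == pytest.approx(0.0008156, rel=5e-4)

    def test_zero_statistic(self):
        assert ig.chisq_sf(0.0, 5) == 1.0

    def test_closed_form_df2(self):
        assert ig.chisq_sf(2 * np.log(4), 2) == pytest.approx(0.25, rel=1e-12)

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            ig.chisq_sf(-1.0, 2)
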