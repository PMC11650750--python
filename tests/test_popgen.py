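"""AMOVA, PCoA, IBD, Mantel and exact tests against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from chloropop import popgen as pg


def make_colonies(spec, rng=None, freqs=None):
    """spec: list of (region, reef, n). Profiles random unless fixed."""
    rng = rng or np.random.default_rng(0)
    labels = ["U1", "U2", "U3", "L"]
    out = []
    cid = 0
    for region, reef, n, *fixed in spec:
        for _ in range(n):
            cid += 1
            if fixed:
                prof = fixed[0]
            elif freqs is not None:
                p = freqs[(region, reef)]
                prof = labels[rng.choice(len(labels), p=p)]
            else:
                prof = labels[rng.integers(0, len(labels))]
            out.append(pg.ColonyRecord(str(cid), reef, region, prof))
    return out


def brute_force_ss(colonies, d2):
    """Direct pair-enumeration AMOVA sums of squares."""

    def ss(group):
        return sum(
            d2(a.profile, b.profile)
            for a, b in itertools.combinations(group, 2)
        ) / len(group)

    reefs = {c.reef_id for c in colonies}
    regions = {c.region_id for c in colonies}
    total = ss(colonies)
    wp = sum(ss([c for c in colonies if c.reef_id == r]) for r in reefs)
    reg = sum(ss([c for c in colonies if c.region_id == g]) for g in regions)
    return total - reg, reg - wp, wp, total


class TestHaplotypeDistance:
    def test_modes(self, panel):
        assert pg.haplotype_distance("U1", "U1") == 0.0
        assert pg.haplotype_distance("U1", "L") == 1.0
        # U1 and U2 differ at exactly one synthetic panel site
        assert pg.haplotype_distance("U1", "U2", "panel_snp_count", panel) == 1.0
        # U1 vs L differ at the five U/L-splitting sites
        assert pg.haplotype_distance("U1", "L", "panel_snp_count", panel) == 5.0

    def test_unknown_label_raises(self, panel):
        with pytest.raises(KeyError):
            pg.haplotype_distance("U1", "ZZ", "panel_snp_count", panel)


class TestAmova:
    def test_complete_fixation(self):
        cols = make_colonies([("g1", "r1", 10, "U1"), ("g1", "r2", 10, "L"),
                              ("g2", "r3", 10, "U2"), ("g2", "r4", 10, "U3")])
        res = pg.amova(cols, n_perm=0)
        assert res.phi["phi_pt"] == pytest.approx(1.0)
        assert res.rows[2].ss == 0.0

    def test_single_profile_is_degenerate_na(self):
        cols = make_colonies([("g1", "r1", 5, "U1"), ("g1", "r2", 5, "U1"),
                              ("g2", "r3", 5, "U1"), ("g2", "r4", 5, "U1")])
        res = pg.amova(cols, n_perm=99, seed=0)
        assert res.degenerate
        assert np.isnan(res.phi["phi_pt"])
        assert res.total_ss == 0.0

    @pytest.mark.parametrize("mode", ["mismatch01", "panel_snp_count"])
    def test_ss_match_bruteforce_oracle(self, mode, panel):
        rng = np.random.default_rng(42)
        spec = [(f"g{g}", f"r{g}{p}", int(rng.integers(5, 15)))
                for g in range(3) for p in range(3)]
        cols = make_colonies(spec, rng=rng)
        res = pg.amova(cols, distance_mode=mode, panel=panel, n_perm=0)

        def d2(a, b):
            d = pg.haplotype_distance(a, b, mode, panel)
            return d * d

        ar, ap, wp, total = brute_force_ss(cols, d2)
        assert res.rows[0].ss == pytest.approx(ar, abs=1e-10)
        assert res.rows[1].ss == pytest.approx(ap, abs=1e-10)
        assert res.rows[2].ss == pytest.approx(wp, abs=1e-10)
        assert res.total_ss == pytest.approx(total, abs=1e-10)
        assert sum(r.df for r in res.rows) == len(cols) - 1

    def test_ss_additivity_and_percent_sum(self):
        rng = np.random.default_rng(3)
        spec = [(f"g{g}", f"r{g}{p}", 8) for g in range(3) for p in range(4)]
        cols = make_colonies(spec, rng=rng)
        res = pg.amova(cols, n_perm=0, clamp_negative=True)
        assert sum(r.percent for r in res.rows) == pytest.approx(100.0, abs=0.01)

    def test_structure_detected_with_significant_p(self):
        freqs = {}
        rng = np.random.default_rng(5)
        spec = []
        for g in range(3):
            for p in range(3):
                spec.append((f"g{g}", f"r{g}{p}", 12))
                base = np.ones(4) * 0.04
                base[g] = 0.88
                freqs[(f"g{g}", f"r{g}{p}")] = base
        cols = make_colonies(spec, rng=rng, freqs=freqs)
        res = pg.amova(cols, n_perm=499, seed=9)
        assert res.phi["phi_pt"] > 0.4
        assert res.p_values["phi_pt"] <= 0.01

    def test_needs_two_reefs(self):
        cols = make_colonies([("g1", "r1", 10)])
        with pytest.raises(ValueError, match=">= 2 reefs"):
            pg.amova(cols, n_perm=0)


class TestPairwisePhipt:
    def test_identical_composition_nonpositive(self):
        cols = make_colonies([("g", "r1", 10, "U1"), ("g", "r2", 10, "U1"),
                              ("g", "r3", 5, "L")])
        phi, _ = pg.pairwise_phipt(cols)
        assert np.isnan(phi.loc["r1", "r2"]) or phi.loc["r1", "r2"] <= 0

    def test_fixed_pair_is_one(self):
        cols = make_colonies([("g", "r1", 10, "U1"), ("g", "r2", 10, "L")])
        phi, _ = pg.pairwise_phipt(cols)
        assert phi.loc["r1", "r2"] == pytest.approx(1.0)

    def test_matches_independent_two_level_amova(self):
        """4-reef mosaic: every entry equals a from-scratch two-level
        decomposition done directly on that reef pair."""
        rng = np.random.default_rng(8)
        cols = make_colonies(
            [("g", f"r{p}", 12) for p in range(4)], rng=rng
        )
        phi, _ = pg.pairwise_phipt(cols)
        for a, b in itertools.combinations(["r0", "r1", "r2", "r3"], 2):
            pair = [c for c in cols if c.reef_id in (a, b)]
            # oracle: explicit SS -> MS -> variance components
            na = sum(1 for c in pair if c.reef_id == a)
            nb = len(pair) - na
            d2 = lambda x, y: 0.0 if x.profile == y.profile else 1.0
            ss_t = sum(d2(x, y) for x, y in itertools.combinations(pair, 2)) / len(pair)
            ss_w = sum(
                sum(d2(x, y) for x, y in itertools.combinations(grp, 2)) / len(grp)
                for grp in ([c for c in pair if c.reef_id == a],
                            [c for c in pair if c.reef_id == b])
            )
            ms_a = (ss_t - ss_w) / 1
            ms_w = ss_w / (len(pair) - 2)
            n_prime = (len(pair) - (na**2 + nb**2) / len(pair)) / 1
            va = (ms_a - ms_w) / n_prime
            expected = va / (va + ms_w)
            assert phi.loc[a, b] == pytest.approx(expected, abs=1e-12)


class TestPcoa:
    def test_two_items_single_axis(self):
        res = pg.pcoa(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert res.coordinates.shape[1] == 1
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-1.0, 1.0])
        assert res.percent[0] == pytest.approx(100.0)

    def test_collinear_points_single_axis(self):
        x = np.arange(5.0)[:, None]
        res = pg.pcoa(squareform(pdist(x)))
        assert res.percent[0] == pytest.approx(100.0, abs=1e-6)

    def test_distances_reconstructed_from_axes(self):
        rng = np.random.default_rng(2)
        pts = rng.random((8, 4))
        d = squareform(pdist(pts))
        res = pg.pcoa(d)
        recon = squareform(pdist(res.coordinates))
        assert np.abs(recon - d).max() < 1e-8
        assert res.percent.sum() == pytest.approx(100.0)
        assert (np.diff(res.percent) <= 1e-9).all()

    def test_matches_skbio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(4)
        pts = rng.random((7, 3))
        d = squareform(pdist(pts))
        ours = pg.pcoa(d)
        theirs = skbio_pcoa(d, number_of_dimensions=3)
        assert np.allclose(
            ours.percent[:3] / 100,
            theirs.proportion_explained.to_numpy()[:3],
            atol=1e-8,
        )

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            pg.pcoa(np.zeros((2, 3)))


class TestIbdRegression:
    def test_exact_linear_cline_r2_one(self):
        # reefs at 0/10/20/30 km; bins chosen so pair distances sit at
        # bin midpoints; genetic distance proportional to km
        pos = np.array([0.0, 10.0, 20.0, 30.0])
        km = np.abs(pos[:, None] - pos[None, :])
        gd = 0.01 * km
        res = pg.ibd_regression(gd, km, bin_edges=np.array([0, 5, 15, 25, 35.0]))
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.01)

    def test_constant_genetic_distance(self):
        pos = np.array([0.0, 10.0, 20.0, 30.0])
        km = np.abs(pos[:, None] - pos[None, :])
        gd = np.full_like(km, 0.3)
        np.fill_diagonal(gd, 0.0)
        res = pg.ibd_regression(gd, km, bin_edges=np.array([0, 5, 15, 25, 35.0]))
        assert res.slope == 0.0
        assert res.r_squared == 0.0

    def test_default_bins_cover_88km(self):
        edges = pg.default_ibd_bins()
        assert edges[0] == 0 and edges[1] == 1 and edges[2] == 2
        assert edges[-1] == 88.0
        assert np.allclose(np.diff(edges[2:]), 2.0)

    def test_slope_recovered_within_ols_ci(self):
        """Noisy planted cline: the planted slope falls inside the OLS 95%
        CI in >= 90 of 100 replicates (pair noise scaled by sqrt(bin size)
        so bin means are homoscedastic, as the OLS interval assumes)."""
        rng = np.random.default_rng(6)
        pos = np.linspace(0, 80, 12)
        km = np.abs(pos[:, None] - pos[None, :])
        edges = pg.default_ibd_bins(km.max())
        iu = np.triu_indices(len(pos), 1)
        which = np.searchsorted(edges, km[iu], side="left") - 1
        counts = np.bincount(which, minlength=len(edges) - 1)
        scale = np.zeros_like(km)
        scale[iu] = 0.01 * np.sqrt(counts[which])
        scale = scale + scale.T
        hits = 0
        for _ in range(100):
            noise = np.triu(rng.normal(0, 1, km.shape), 1) * scale
            gd = 0.005 * km + noise + noise.T
            np.fill_diagonal(gd, 0.0)
            res = pg.ibd_regression(gd, km)
            se = np.sqrt(
                np.sum((res.bin_mean - res.intercept - res.slope * res.bin_mid) ** 2)
                / (len(res.bin_mid) - 2)
                / np.sum((res.bin_mid - res.bin_mid.mean()) ** 2)
            )
            t = stats.t.ppf(0.975, len(res.bin_mid) - 2)
            if abs(res.slope - 0.005) <= t * se:
                hits += 1
        assert hits >= 90

    def test_single_bin_degenerate(self):
        km = np.array([[0.0, 3.0], [3.0, 0.0]])
        gd = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="bins"):
            pg.ibd_regression(gd, km, bin_edges=np.array([0.0, 10.0]))


class TestMantel:
    def test_identity_r_one(self):
        rng = np.random.default_rng(1)
        d = squareform(pdist(rng.random((6, 2))))
        res = pg.mantel(d, d, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_matches_bruteforce_correlation(self):
        rng = np.random.default_rng(9)
        a = squareform(pdist(rng.random((5, 2))))
        b = squareform(pdist(rng.random((5, 2))))
        res = pg.mantel(a, b, n_perm=0)
        pairs_a = [a[i, j] for i in range(5) for j in range(i)]
        pairs_b = [b[i, j] for i in range(5) for j in range(i)]
        assert res.r == pytest.approx(np.corrcoef(pairs_a, pairs_b)[0, 1])

    def test_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        rng = np.random.default_rng(10)
        a = squareform(pdist(rng.random((7, 2))))
        b = squareform(pdist(rng.random((7, 2))))
        ours = pg.mantel(a, b, n_perm=0)
        r, _, _ = sk_mantel(DistanceMatrix(a), DistanceMatrix(b),
                            permutations=0)
        assert ours.r == pytest.approx(r, abs=1e-12)

    def test_invariant_to_joint_relabeling(self):
        rng = np.random.default_rng(12)
        a = squareform(pdist(rng.random((6, 2))))
        b = squareform(pdist(rng.random((6, 2))))
        perm = rng.permutation(6)
        r1 = pg.mantel(a, b, n_perm=0).r
        r2 = pg.mantel(a[np.ix_(perm, perm)], b[np.ix_(perm, perm)],
                       n_perm=0).r
        assert r1 == pytest.approx(r2)


class TestThermalDistance:
    def test_closed_forms(self):
        d = pg.thermal_distance([(29.0, 0.5), (30.0, 0.5), (29.0, 0.5)])
        assert d[0, 2] == 0.0
        assert d[0, 1] == pytest.approx(1.0)

    def test_matches_per_pair_oracle(self):
        rng = np.random.default_rng(13)
        reefs = [(29 + rng.random(), 0.3 + rng.random()) for _ in range(6)]
        d = pg.thermal_distance(reefs)
        for i, j in itertools.combinations(range(6), 2):
            expected = np.sqrt(
                (reefs[i][0] - reefs[j][0]) ** 2
                + (reefs[i][1] - reefs[j][1]) ** 2
            )
            assert d[i, j] == pytest.approx(expected)

    def test_missing_field_raises(self):
        with pytest.raises(ValueError, match="missing"):
            pg.thermal_distance([(29.0, np.nan)])


class TestExactTests:
    def test_published_2x2(self):
        assert pg.fisher_exact_2x2([[9, 7], [10, 19]]) == pytest.approx(
            0.2121, abs=0.0005
        )

    def test_diagonal_table_matches_enumeration(self):
        """[[5,0],[0,5]]: full hypergeometric enumeration gives 2/252."""
        p = pg.fisher_exact_2x2([[5, 0], [0, 5]])
        obs_p = stats.hypergeom.pmf(5, 10, 5, 5)
        total = sum(
            stats.hypergeom.pmf(k, 10, 5, 5)
            for k in range(6)
            if stats.hypergeom.pmf(k, 10, 5, 5) <= obs_p * (1 + 1e-9)
        )
        assert p == pytest.approx(total)
        assert p == pytest.approx(2 / 252)

    def test_zero_margin_is_one(self):
        assert pg.fisher_exact_2x2([[3, 5], [0, 0]]) == pytest.approx(1.0)

    def test_negative_cell_raises(self):
        with pytest.raises(ValueError, match="non-negative"):
            pg.fisher_exact_2x2([[1, -1], [2, 3]])

    def test_chi2_zero_for_independent_table(self):
        stat, df, p = pg.chi_square_independence([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_chi2_matches_direct_sum(self):
        table = np.array([[30, 20, 5, 10, 12], [15, 25, 40, 8, 9]], dtype=float)
        stat, df, p = pg.chi_square_independence(table)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert stat == pytest.approx(((table - exp) ** 2 / exp).sum())
        assert df == 4

    def test_chi2_drops_zero_margins_with_warning(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            stat, df, p = pg.chi_square_independence(
                [[10, 0, 5], [8, 0, 12]]
            )
        assert df == 1


class TestReefDistances:
    def test_frequency_distance_zero_for_identical(self):
        cols = make_colonies([("g", "r1", 10, "U1"), ("g", "r2", 10, "U1")])
        d = pg.reef_genetic_distance(cols, method="frequency")
        assert d.loc["r1", "r2"] == 0.0

    def test_geographic_distance_from_coords(self):
        cols = [
            pg.ColonyRecord("1", "a", "g", "U1", x_km=0.0, y_km=0.0),
            pg.ColonyRecord("2", "b", "g", "L", x_km=3.0, y_km=4.0),
        ]
        d = pg.reef_geographic_distance(cols)
        assert d.loc["a", "b"] == pytest.approx(5.0)
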