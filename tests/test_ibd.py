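"""Geographic distances, Mantel test, RMA regression, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coastibd import ibd
from coastibd.simdata import fixture_paper


def _matrix_from(values, kind="km"):
    ids = [str(i) for i in range(len(values))]
    return ibd.PairwiseMatrix(ids, np.asarray(values, dtype=float), kind=kind)


def _sym(n, rng, scale=1.0):
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.random(len(iu[0])) * scale
    return m + m.T


class TestGreatCircle:
    def test_identical_points(self):
        assert ibd.great_circle_km(48.0, -125.0, 48.0, -125.0) == 0.0

    def test_one_degree_latitude(self):
        d = ibd.great_circle_km(10.0, 30.0, 11.0, 30.0)
        assert d == pytest.approx(111.19, abs=0.01)

    def test_against_spherical_law_of_cosines(self):
        sites = fixture_paper()["sites"]
        a, b = sites.iloc[0], sites.iloc[1]
        d = ibd.great_circle_km(a["lat"], a["lon"], b["lat"], b["lon"])
        # independent spherical-geometry oracle
        p1, p2 = math.radians(a["lat"]), math.radians(b["lat"])
        dl = math.radians(b["lon"] - a["lon"])
        oracle = 6371.0 * math.acos(
            math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl))
        assert d == pytest.approx(oracle, rel=0.005)

    def test_invalid_coordinates(self):
        with pytest.raises(ValueError):
            ibd.great_circle_km(95, 0, 0, 0)


class TestCoastDistance:
    def test_sites_projecting_to_same_point(self):
        coast = np.array([[0.0, 0.0], [1.0, 0.0]])
        sites = pd.DataFrame({"site_id": ["a", "b"],
                              "lat": [0.5, 0.5], "lon": [0.1, 0.2]})
        mat, _ = ibd.coast_distance(sites, coast)
        assert mat.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_straight_coast_reproduces_great_circle(self):
        coast = np.array([[0.0, 0.0], [2.0, 0.0]])
        sites = pd.DataFrame({"site_id": ["a", "b"],
                              "lat": [0.2, 1.7], "lon": [0.0, 0.0]})
        mat, _ = ibd.coast_distance(sites, coast)
        gc = ibd.great_circle_km(0.2, 0.0, 1.7, 0.0)
        assert mat.values[0, 1] == pytest.approx(gc, rel=1e-3)

    def test_z_shaped_coast_hand_summed(self):
        # three segments: north, east, north again (small area near equator)
        coast = np.array([[0.0, 0.0], [0.5, 0.0], [0.5, 0.5], [1.0, 0.5]])
        sites = pd.DataFrame({"site_id": ["a", "b"],
                              "lat": [0.0, 1.0], "lon": [0.0, 0.5]})
        mat, filled = ibd.coast_distance(sites, coast)
        seg = (ibd.great_circle_km(0, 0, 0.5, 0)
               + ibd.great_circle_km(0.5, 0, 0.5, 0.5)
               + ibd.great_circle_km(0.5, 0.5, 1.0, 0.5))
        assert mat.values[0, 1] == pytest.approx(seg, rel=1e-3)
        assert list(filled["s_km"]) == pytest.approx([0.0, seg], rel=1e-3)

    def test_faraway_site_falls_back_to_great_circle(self):
        coast = np.array([[0.0, 0.0], [1.0, 0.0]])
        sites = pd.DataFrame({"site_id": ["a", "b"],
                              "lat": [0.0, 0.5], "lon": [0.0, 30.0]})
        with pytest.warns(UserWarning, match="fallback"):
            mat, filled = ibd.coast_distance(sites, coast)
        assert filled["gc_fallback"].iloc[1]
        assert mat.values[0, 1] == pytest.approx(
            ibd.great_circle_km(0, 0, 0.5, 30.0))

    def test_coast_at_least_great_circle(self):
        # for sites lying on the polyline, arc length dominates the chord
        coast = np.column_stack([np.linspace(0, 5, 12),
                                 0.5 * np.sin(np.linspace(0, 6, 12))])
        picks = [0, 3, 6, 8, 11]
        sites = pd.DataFrame({
            "site_id": [str(i) for i in range(5)],
            "lat": coast[picks, 0],
            "lon": coast[picks, 1],
        })
        mat, _ = ibd.coast_distance(sites, coast)
        for i in range(5):
            for j in range(i + 1, 5):
                gc = ibd.great_circle_km(sites.lat[i], sites.lon[i],
                                         sites.lat[j], sites.lon[j])
                assert mat.values[i, j] >= gc - 1.0  # km, projection slack


class TestLinearize:
    def test_values(self):
        m = _matrix_from([[0, 0.0025], [0.0025, 0]], kind="fst")
        out = ibd.linearize_fst(m)
        assert out.values[0, 1] == pytest.approx(0.0025063, abs=1e-7)

    def test_negative_input_stays_negative(self):
        m = _matrix_from([[0, -0.0008], [-0.0008, 0]], kind="fst")
        assert ibd.linearize_fst(m).values[0, 1] == pytest.approx(-0.0007994, abs=1e-7)

    def test_zero_and_unity(self):
        z = _matrix_from([[0, 0.0], [0.0, 0]], kind="fst")
        assert ibd.linearize_fst(z).values[0, 1] == 0.0
        bad = _matrix_from([[0, 1.0], [1.0, 0]], kind="fst")
        with pytest.raises(ValueError, match="linearized"):
            ibd.linearize_fst(bad)


class TestMantel:
    def test_perfect_linear_association(self):
        rng = np.random.default_rng(1)
        geo = _sym(6, rng, 100)
        gen = 2e-5 * geo + 1e-3
        r, p = ibd.mantel_test(_matrix_from(geo), _matrix_from(gen, "fst"),
                               n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_r_equals_pearson_on_offdiag(self):
        rng = np.random.default_rng(2)
        geo, gen = _matrix_from(_sym(7, rng)), _matrix_from(_sym(7, rng), "fst")
        r, _ = ibd.mantel_test(geo, gen, n_perm=99, seed=0)
        assert r == stats.pearsonr(geo.offdiag(), gen.offdiag()).statistic

    def test_against_scikit_bio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        geo = _sym(8, rng, 50)
        gen = 1e-5 * geo + _sym(8, rng, 2e-4)
        np.fill_diagonal(gen, 0)
        gen = (gen + gen.T) / 2
        r_ours, _ = ibd.mantel_test(_matrix_from(geo), _matrix_from(gen, "fst"),
                                    n_perm=99, seed=0)
        r_skbio, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(geo),
            skbio_distance.DistanceMatrix(gen),
            method="pearson", permutations=0)
        assert r_ours == pytest.approx(r_skbio, abs=1e-12)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(60):
            geo = _matrix_from(_sym(6, rng, 100))
            gen = _matrix_from(_sym(6, rng, 1e-3), "fst")
            ps.append(ibd.mantel_test(geo, gen, n_perm=99,
                                      seed=int(rng.integers(2**31)))[1])
        assert 0.2 < np.mean(ps) < 0.8


class TestRma:
    def test_exact_linear_data_recovered(self):
        rng = np.random.default_rng(5)
        geo = _sym(6, rng, 500)
        gen = 3e-5 * geo + 2e-3
        fit = ibd.rma_fit(_matrix_from(geo), _matrix_from(gen, "fst"),
                          n_perm=99, seed=0)
        assert fit.slope == pytest.approx(3e-5)
        assert fit.intercept == pytest.approx(2e-3)
        assert fit.ci[0] == pytest.approx(3e-5, abs=1e-12)
        assert fit.ci[1] == pytest.approx(3e-5, abs=1e-12)

    def test_axis_swap_inverts_slope(self):
        rng = np.random.default_rng(6)
        a = _matrix_from(_sym(6, rng, 100))
        b = _matrix_from(_sym(6, rng, 1.0), "fst")
        s_ab = ibd.rma_fit(a, b, n_perm=99, seed=0).slope
        s_ba = ibd.rma_fit(b, a, n_perm=99, seed=0).slope
        assert s_ab == pytest.approx(1 / s_ba)

    def test_slope_is_sd_ratio_on_toy(self):
        # 5 sites => 10 pairs; oracle from the sd-ratio definition
        rng = np.random.default_rng(7)
        geo = _sym(5, rng, 300)
        gen = 1e-5 * geo + _sym(5, rng, 5e-4)
        gx, gy = _matrix_from(geo), _matrix_from(gen, "fst")
        fit = ibd.rma_fit(gx, gy, n_perm=99, seed=0)
        x, y = gx.offdiag(), gy.offdiag()
        sign = np.sign(stats.pearsonr(x, y).statistic)
        assert fit.slope == pytest.approx(sign * np.std(y, ddof=1) / np.std(x, ddof=1),
                                          abs=1e-15)

    def test_rma_attenuation_vs_ols(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = rng.integers(5, 9)
            gx = _matrix_from(_sym(n, rng, 100))
            gy = _matrix_from(_sym(n, rng, 1.0), "fst")
            fit = ibd.rma_fit(gx, gy, n_perm=99, seed=0)
            ols = stats.linregress(gx.offdiag(), gy.offdiag()).slope
            assert abs(fit.slope) >= abs(ols) - 1e-12

    def test_too_few_sites_no_ci(self):
        rng = np.random.default_rng(9)
        gx = _matrix_from(_sym(3, rng, 100))
        gy = _matrix_from(_sym(3, rng, 1.0), "fst")
        fit = ibd.rma_fit(gx, gy, n_perm=99, seed=0)
        assert math.isnan(fit.ci[0]) and math.isnan(fit.ci[1])

    def test_bootstrap_ci_brackets_slope(self):
        rng = np.random.default_rng(10)
        geo = _sym(8, rng, 400)
        gen = 2e-5 * geo + _sym(8, rng, 3e-4)
        fit = ibd.rma_fit(_matrix_from(geo), _matrix_from(gen, "fst"),
                          n_perm=99, seed=1, ci_method="bootstrap", resamples=200)
        assert fit.ci[0] <= fit.slope <= fit.ci[1]


class TestEquilibriumDiagnostics:
    def _inputs(self):
        rng = np.random.default_rng(11)
        n = 6
        geo = _matrix_from(_sym(n, rng, 500))
        gen = ibd.PairwiseMatrix(geo.ids, 1e-5 * geo.values, kind="fst")
        sites = pd.DataFrame({
            "site_id": geo.ids,
            "lat": np.linspace(42, 52, n),
        })
        div = pd.DataFrame({
            "population": list(geo.ids) * 2,
            "He": rng.uniform(0.4, 0.8, 2 * n),
            "Ar": rng.uniform(2, 10, 2 * n),
        })
        return sites, geo, gen, div

    def test_subrange_fits_and_correlations(self):
        sites, geo, gen, div = self._inputs()
        out = ibd.equilibrium_diagnostics(
            sites, geo, gen, div,
            south_ids=geo.ids[:4], north_ids=geo.ids[2:],
            n_perm=99, seed=0)
        assert out["south_fit"].slope == pytest.approx(1e-5)
        assert out["north_fit"].slope == pytest.approx(1e-5)
        assert -1 <= out["lat_he"]["rho"] <= 1

    def test_constant_diversity_flagged(self):
        sites, geo, gen, div = self._inputs()
        div["He"] = 0.5
        out = ibd.equilibrium_diagnostics(
            sites, geo, gen, div,
            south_ids=geo.ids[:4], north_ids=geo.ids[2:], n_perm=99, seed=0)
        assert out["lat_he"]["flag"] == "constant diversity"
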