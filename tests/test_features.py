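"""Organisational features: shell densities, Voronoi-derived features,
pooled z-scoring and feature-class recovery."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nuqloud import features as F
from nuqloud import geometry as G
from nuqloud import synthetic as S
from nuqloud.datatypes import FeatureConfig


def lattice_points(n=5, spacing=10.0):
    xs = np.arange(n) * spacing
    return np.array([[x, y, z] for x in xs for y in xs for z in xs])


class TestShellDensities:
    def test_isolated_point_all_zero(self):
        pts = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        assert np.all(F.shell_densities(pts) == 0.0)

    def test_single_neighbour_in_middle_shell(self):
        pts = np.array([[0.0, 0, 0], [15.0, 0, 0]])
        d = F.shell_densities(pts)
        expected = 1.0 / (4.0 / 3.0 * np.pi * (20.0 ** 3 - 10.0 ** 3))
        assert d[0, 0] == 0.0
        assert d[0, 1] == pytest.approx(expected, rel=1e-12)
        assert d[0, 2] == 0.0
        assert expected == pytest.approx(3.411e-5, rel=1e-3)

    def test_poisson_calibration(self):
        lam = 0.02
        rng = np.random.default_rng(0)
        n = rng.poisson(lam * 100.0 ** 3)
        pts = rng.uniform(0, 100, (n, 3))
        d = F.shell_densities(pts)
        interior = np.all((pts > 30) & (pts < 70), axis=1)
        assert np.allclose(d[interior].mean(axis=0), lam, rtol=0.03)

    def test_dilution_scales_densities(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 120, (20000, 3))
        keep = rng.uniform(size=len(pts)) < 0.5
        interior = np.all((pts > 30) & (pts < 90), axis=1)
        full = F.shell_densities(pts)[interior].mean(axis=0)
        thin = F.shell_densities(pts[keep])[interior[keep]].mean(axis=0)
        assert np.allclose(thin / full, 0.5, rtol=0.05)

    def test_bad_radii_rejected(self):
        with pytest.raises(ValueError):
            F.shell_densities(np.zeros((2, 3)), radii=(10, 10, 30))


class TestCellFeatures:
    def test_two_point_definitions(self):
        tess = G.restricted_voronoi(
            np.array([[0.0, 0, 0], [10.0, 0, 0]]), 100.0)
        frame, isolated = F.cell_features(tess)
        assert np.allclose(frame["voronoi_density"], 0.1)
        assert np.allclose(frame["n_neighbours"], 1)
        assert not isolated.any()

    def test_lattice_interior_symmetry(self):
        tess = G.restricted_voronoi(lattice_points(), 100.0)
        frame, _ = F.cell_features(tess)
        ci = 2 * 25 + 2 * 5 + 2
        assert frame.loc[ci, "centroid_offset"] < 1e-6
        assert frame.loc[ci, "polarity"] < 1e-7
        assert frame.loc[ci, "voronoi_volume"] == pytest.approx(1000, rel=1e-6)
        nbh = F.neighbourhood_stats(tess, frame)
        assert nbh.loc[ci, "nbh_mean_volume"] == pytest.approx(1000, rel=1e-6)
        assert nbh.loc[ci, "nbh_std_volume"] == pytest.approx(0.0, abs=1e-3)

    def test_neighbourhood_population_std(self):
        # star: centre with three collinear-free neighbours carrying values
        tess = G.restricted_voronoi(np.array(
            [[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]]), 100.0)
        frame, _ = F.cell_features(tess)
        frame = frame.copy()
        frame["voronoi_volume"] = [0.0, 1.0, 2.0, 3.0]
        nbh = F.neighbourhood_stats(tess, frame)
        assert nbh.loc[0, "nbh_mean_volume"] == pytest.approx(2.0)
        assert nbh.loc[0, "nbh_std_volume"] == pytest.approx(
            np.std([1, 2, 3]), rel=1e-12)  # population form ~0.8165

    def test_single_neighbour_std_zero(self):
        tess = G.restricted_voronoi(
            np.array([[0.0, 0, 0], [10.0, 0, 0]]), 100.0)
        frame, _ = F.cell_features(tess)
        nbh = F.neighbourhood_stats(tess, frame)
        assert np.all(nbh[["nbh_std_volume", "nbh_std_n_neighbours",
                           "nbh_std_centroid_offset"]].to_numpy() == 0.0)


class TestPipelineAndZscore:
    def test_exactly_14_feature_columns(self, small_embryo_features):
        assert len(small_embryo_features.feature_names) == 14
        assert set(small_embryo_features.feature_names) == set(F.FEATURE_NAMES)

    def test_zscore_own_params_unit_moments(self, small_embryo_features):
        z = F.zscore(small_embryo_features)
        x = z.values
        assert np.allclose(x.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(x.std(axis=0), 1.0, atol=1e-9)

    def test_zscore_roundtrip_and_stored_params(self, small_embryo_features):
        z = F.zscore(small_embryo_features)
        back = F.inverse_zscore(z)
        assert np.allclose(back.values, small_embryo_features.values,
                           rtol=1e-12, atol=1e-12)
        z2 = F.zscore(small_embryo_features, params=z.zscore_params)
        assert np.allclose(z2.values, z.values)

    def test_constant_feature_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        df["sample_id"] = "s"
        df["nucleus_id"] = range(3)
        table = F.FeatureTable(df.set_index(["sample_id", "nucleus_id"]),
                               feature_names=("a", "b"))
        with pytest.raises(ValueError, match="b"):
            F.zscore(table)

    def test_pooled_zscore_preserves_sample_differences(self):
        rng = np.random.default_rng(0)
        rows = []
        for sid, mu in (("s1", 0.0), ("s2", 5.0)):
            for i in range(50):
                rows.append({"sample_id": sid, "nucleus_id": i,
                             "a": rng.normal(mu, 1.0),
                             "b": rng.normal(0.0, 1.0)})
        table = F.FeatureTable(
            pd.DataFrame(rows).set_index(["sample_id", "nucleus_id"]),
            feature_names=("a", "b"))
        z = F.zscore(table)
        sids = z.sample_ids
        m1 = z.values[sids == "s1", 0].mean()
        m2 = z.values[sids == "s2", 0].mean()
        assert m2 - m1 > 1.0  # inter-sample shift survives pooled scaling

    def test_features_rigid_motion_invariant(self):
        cloud = S.make_amorphous(3e-3, region=("box", (100.0, 100.0, 100.0)),
                                 hardcore=2.0, seed=5)
        ft1 = F.compute_features(cloud)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moved = S.SampleCloud(
            sample_id="m", nucleus_ids=cloud.nucleus_ids,
            positions=cloud.positions @ R.T + [7.0, -4.0, 2.0])
        ft2 = F.compute_features(moved)
        # the bounding solid is orientation-fixed, so boundary-cell geometry
        # (and the neighbourhood stats of cells touching them) may rotate;
        # deep cells with fully interior neighbourhoods are invariant
        pos = cloud.positions
        deep = np.all((pos > 30.0) & (pos < 70.0), axis=1)
        a = ft1.values[deep]
        b = ft2.values[deep]
        scale = np.abs(a).mean(axis=0) + 1e-12
        assert np.max(np.abs(a - b) / scale) < 1e-6


class TestArchetypeSignatures:
    def test_volume_density_anticorrelation(self, small_embryo_features):
        d = small_embryo_features.data
        r = np.corrcoef(d["voronoi_volume"], d["density_0_10"])[0, 1]
        assert r < -0.5

    def test_population_feature_directions(self, small_embryo_features):
        # amorphous: denser, smaller cells, more neighbour-count variability
        d = small_embryo_features.data
        interior = d["interior"].to_numpy()
        am = d[interior & (d["population"] == "amorphous")]
        cr = d[interior & (d["population"] == "crystalline")]
        for col, sign in (("density_0_10", 1), ("density_10_20", 1),
                          ("density_20_30", 1), ("voronoi_volume", -1),
                          ("nbh_std_n_neighbours", 1)):
            u = stats.mannwhitneyu(am[col], cr[col],
                                   alternative="greater" if sign > 0
                                   else "less")
            assert u.pvalue < 1e-3, col

    def test_linear_separability_of_populations(self, small_embryo_features):
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        d = small_embryo_features.data
        interior = d["interior"].to_numpy()
        x = StandardScaler().fit_transform(
            small_embryo_features.values[interior])
        y = (d["population"].to_numpy()[interior] == "amorphous")
        clf = LogisticRegression(max_iter=2000).fit(x, y)
        assert clf.score(x, y) >= 0.95


class TestFeatureClasses:
    def test_duplicated_feature_co_clusters(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(200, 13))
        x = np.column_stack([base, base[:, 0] + rng.normal(
            0, 1e-3, 200)])
        names = list(F.FEATURE_NAMES)
        df = pd.DataFrame(x, columns=names)
        df["sample_id"] = "s"
        df["nucleus_id"] = range(200)
        table = F.FeatureTable(df.set_index(["sample_id", "nucleus_id"]))
        cmap = F.classify_features(table)
        # duplicate pair: first and last columns
        assert cmap.classes[names[0]] == cmap.classes[names[-1]]

    def test_block_structure_recovered(self):
        rng = np.random.default_rng(4)
        blocks = {"density": F.DENSITY_FEATURES,
                  "anisotropy": F.ANISOTROPY_FEATURES,
                  "irregularity": F.IRREGULARITY_FEATURES}
        n = 400
        cols = {}
        for bname, members in blocks.items():
            shared = rng.normal(size=n)
            for m in members:
                cols[m] = np.sqrt(0.9) * shared + np.sqrt(0.1) * rng.normal(
                    size=n)
        df = pd.DataFrame(cols)[list(F.FEATURE_NAMES)]
        df["sample_id"] = "s"
        df["nucleus_id"] = range(n)
        table = F.FeatureTable(df.set_index(["sample_id", "nucleus_id"]))
        cmap = F.classify_features(table)
        for bname, members in blocks.items():
            assert all(cmap.classes[m] == bname for m in members), bname

    def test_density_features_co_cluster_on_embryo(self, small_embryo_z):
        cmap = F.classify_features(small_embryo_z)
        classes = [cmap.classes[f] for f in F.DENSITY_FEATURES]
        majority = max(set(classes), key=classes.count)
        assert classes.count(majority) >= 3


class TestConfig:
    def test_shell_radii_validation(self):
        with pytest.raises(ValueError):
            FeatureConfig(shell_radii=(10, 5, 30))
        with pytest.raises(ValueError):
            FeatureConfig(shell_radii=(-1, 5, 30))
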