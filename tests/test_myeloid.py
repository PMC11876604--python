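import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, spearmanr

import tmecomm as tc
from tmecomm.myeloid import (
    classify_differentiation,
    cluster_and_mst,
    fit_division_boundary,
    gene_trends,
    polarization_score,
    project_pseudotime,
)


def _coords(points):
    return pd.DataFrame(
        np.asarray(points, dtype=float),
        columns=["axis1", "axis2"],
        index=[f"c{i}" for i in range(len(points))],
    )


def _three_collinear_clusters(rng, n=120):
    centers = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
    pts = np.vstack([c + rng.normal(0, 0.08, size=(n, 2)) for c in centers])
    coords = _coords(pts)
    flags = pd.Series(False, index=coords.index)
    flags.iloc[:n] = True  # cluster at the origin is monocyte dominated
    return coords, flags, centers


class TestClusterAndMST:
    def test_collinear_clusters_form_rooted_path(self, rng):
        coords, flags, centers = _three_collinear_clusters(rng)
        clusters = cluster_and_mst(coords, flags, K_range=[3], seed=0)
        # brute-force MST on this instance is the path along the line
        order = np.argsort(clusters.centroids[:, 0])
        edges = set(map(frozenset, clusters.tree.edges))
        assert edges == {
            frozenset((order[0], order[1])),
            frozenset((order[1], order[2])),
        }
        assert clusters.root == order[0]

    def test_root_is_argmax_monocyte_fraction(self, rng):
        coords, flags, _ = _three_collinear_clusters(rng)
        # move the flags to the far cluster
        flags[:] = False
        flags.iloc[-120:] = True
        clusters = cluster_and_mst(coords, flags, K_range=[3], seed=0)
        assert clusters.centroids[clusters.root, 0] == pytest.approx(4.0, abs=0.1)

    def test_single_cluster_range_rejected(self, rng):
        coords, flags, _ = _three_collinear_clusters(rng)
        with pytest.raises(ValueError, match="at least 2"):
            cluster_and_mst(coords, flags, K_range=[1])

    def test_no_monocytes_rejected(self, rng):
        coords, flags, _ = _three_collinear_clusters(rng)
        with pytest.raises(ValueError, match="monocyte"):
            cluster_and_mst(coords, flags & False, K_range=[3])


class TestPseudotime:
    @pytest.fixture()
    def path_clusters(self, rng):
        coords, flags, _ = _three_collinear_clusters(rng)
        return coords, cluster_and_mst(coords, flags, K_range=[3], seed=0)

    def test_root_centroid_has_zero_pseudotime(self, path_clusters):
        coords, clusters = path_clusters
        probe = _coords([clusters.centroids[clusters.root]])
        pt = project_pseudotime(probe, clusters)
        assert pt["pseudotime"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_leaf_centroid_has_full_path_length(self, path_clusters):
        coords, clusters = path_clusters
        order = np.argsort(clusters.centroids[:, 0])
        leaf = order[-1]
        total = sum(clusters.tree.edges[u, v]["weight"] for u, v in clusters.tree.edges)
        probe = _coords([clusters.centroids[leaf]])
        pt = project_pseudotime(probe, clusters)
        assert pt["pseudotime"].iloc[0] == pytest.approx(total, rel=1e-9)

    def test_monotone_along_line(self, path_clusters):
        coords, clusters = path_clusters
        pt = project_pseudotime(coords, clusters)
        rho = spearmanr(coords["axis1"], pt["pseudotime"]).statistic
        assert rho > 0.95


class TestDifferentiation:
    def test_bimodal_pseudotime_classified_accurately(self, rng):
        lo = rng.normal(0.1, 0.05, 500)
        hi = rng.normal(1.0, 0.1, 500)
        pt = pd.Series(np.r_[lo, hi], index=[f"c{i}" for i in range(1000)])
        state = classify_differentiation(pt, seed=0)
        truth = np.r_[np.zeros(500), np.ones(500)]
        acc = ((state == "differentiated").to_numpy() == truth).mean()
        assert acc > 0.95

    def test_degenerate_pseudotime_single_state(self):
        pt = pd.Series(np.full(50, 0.3))
        with pytest.warns(UserWarning, match="identical"):
            state = classify_differentiation(pt)
        assert (state == "undifferentiated").all()

    def test_order_invariance(self, rng):
        vals = np.r_[rng.normal(0.1, 0.05, 100), rng.normal(1.0, 0.1, 100)]
        idx = [f"c{i}" for i in range(200)]
        s1 = classify_differentiation(pd.Series(vals, index=idx), seed=0)
        perm = rng.permutation(200)
        s2 = classify_differentiation(pd.Series(vals[perm], index=np.array(idx)[perm]), seed=0)
        assert (s2.loc[idx] == s1).all()


class TestBoundary:
    def test_symmetric_cloud_gives_flat_boundary(self, rng):
        x = rng.uniform(0, 1, 400)
        y = rng.normal(0, 0.2, 400)
        b = fit_division_boundary(_coords(np.c_[x, y]))
        grid = np.linspace(0.05, 0.95, 50)
        assert np.max(np.abs(b(grid))) < 0.05

    def test_constant_height_recovered(self, rng):
        x = rng.uniform(0, 1, 100)
        b = fit_division_boundary(_coords(np.c_[x, np.full(100, 0.7)]))
        assert np.allclose(b(np.linspace(0, 1, 20)), 0.7, atol=1e-6)

    def test_extrapolation_clamps_to_endpoints(self, rng):
        x = np.linspace(0, 1, 100)
        y = x**2
        b = fit_division_boundary(_coords(np.c_[x, y]))
        assert b(5.0) == pytest.approx(float(b(1.0)))
        assert b(-5.0) == pytest.approx(float(b(0.0)))

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError, match="10"):
            fit_division_boundary(_coords(rng.normal(size=(10, 2))))


class TestPolarization:
    @staticmethod
    def _flat_boundary():
        class Flat:
            def __call__(self, x):
                return np.zeros_like(np.asarray(x, dtype=float))

        return Flat()

    def test_cell_on_boundary_scores_zero(self):
        coords = _coords([[0.5, 0.0]])
        pt = pd.Series([0.7], index=coords.index)
        pol = polarization_score(coords, pt, self._flat_boundary())
        assert pol["polarization"].iloc[0] == 0.0

    def test_sign_convention_above_boundary_positive(self):
        coords = _coords([[0.5, 0.4], [0.5, -0.4]])
        pt = pd.Series([0.5, 0.5], index=coords.index)
        pol = polarization_score(coords, pt, self._flat_boundary())
        assert pol["polarization"].tolist() == [0.5, -0.5]

    def test_marker_score_flips_orientation(self):
        coords = _coords([[0.5, 0.4], [0.5, -0.4]])
        pt = pd.Series([0.5, 0.5], index=coords.index)
        m2 = pd.Series([0.0, 1.0], index=coords.index)  # M2 marker below
        pol = polarization_score(coords, pt, self._flat_boundary(), m2_scores=m2)
        assert pol["polarization"].tolist() == [-0.5, 0.5]

    def test_m1_label_below_mean_score(self, rng):
        coords = _coords(np.c_[rng.uniform(0, 1, 100), rng.normal(0, 0.5, 100)])
        pt = pd.Series(rng.uniform(0, 1, 100), index=coords.index)
        pol = polarization_score(coords, pt, self._flat_boundary())
        below = pol["polarization"] < pol["polarization"].mean()
        assert (pol.loc[below, "m1m2"] == "M1").all()
        assert (pol.loc[~below, "m1m2"] == "M2").all()


class TestEndToEndRecovery:
    def test_manifold_branch_and_pseudotime_recovery(self):
        """Branch sign and arc-length recovered from a noisy Y-manifold."""
        coords, truth = tc.simulate_myeloid_manifold(1500, noise_sd=0.05, seed=11)
        flags = pd.Series(truth.cells["arc_length"] < 0.3, index=coords.index)
        clusters = cluster_and_mst(coords, flags, K_range=range(2, 26), seed=0)
        pt = project_pseudotime(coords, clusters)
        rho = spearmanr(pt["pseudotime"], truth.cells["arc_length"]).statistic
        assert rho > 0.9
        state = classify_differentiation(pt["pseudotime"], seed=0)
        boundary = fit_division_boundary(coords[state == "undifferentiated"])
        pol = polarization_score(coords, pt["pseudotime"], boundary)
        diff = (state == "differentiated").to_numpy()
        branch = truth.cells["branch"].to_numpy()
        eligible = diff & (branch != "root")
        agree = ((pol["side"].to_numpy() > 0) == (branch == "M2"))[eligible]
        assert agree.mean() > 0.9

    def test_orientation_covariance_under_axis_flip(self):
        coords, truth = tc.simulate_myeloid_manifold(600, noise_sd=0.03, seed=4)
        flags = pd.Series(truth.cells["arc_length"] < 0.3, index=coords.index)
        clusters = cluster_and_mst(coords, flags, K_range=range(2, 10), seed=0)
        pt = project_pseudotime(coords, clusters)["pseudotime"]
        state = classify_differentiation(pt, seed=0)
        b = fit_division_boundary(coords[state == "undifferentiated"])
        pol = polarization_score(coords, pt, b)
        flipped = coords.assign(axis2=-coords["axis2"])
        clusters_f = cluster_and_mst(flipped, flags, K_range=range(2, 10), seed=0)
        pt_f = project_pseudotime(flipped, clusters_f)["pseudotime"]
        state_f = classify_differentiation(pt_f, seed=0)
        b_f = fit_division_boundary(flipped[state_f == "undifferentiated"])
        m2 = pd.Series((truth.cells["branch"] == "M2").astype(float), index=coords.index)
        pol_f = polarization_score(flipped, pt_f, b_f, m2_scores=m2)
        # with the M2-marker orientation re-declared, signs agree for most cells
        diff = (state == "differentiated") & (state_f == "differentiated")
        same = np.sign(pol.loc[diff, "polarization"]) == np.sign(pol_f.loc[diff, "polarization"])
        assert same.mean() > 0.9


class TestGeneTrends:
    def test_exact_signal_ranks_first(self, rng):
        n = 300
        pol = pd.Series(rng.uniform(-1, 1, n), index=[f"c{i}" for i in range(n)])
        expr = pd.DataFrame(
            {
                "signal": pol.to_numpy(),
                **{f"noise{j}": rng.normal(size=n) for j in range(10)},
            },
            index=pol.index,
        )
        res = gene_trends(expr, pol)
        assert res.index[0] == "signal"
        assert res.loc["signal", "p"] < 1e-10
        assert res.loc["signal", "direction"] == "increasing"

    def test_constant_gene_has_no_trend(self, rng):
        n = 200
        pol = pd.Series(rng.uniform(-1, 1, n), index=[f"c{i}" for i in range(n)])
        expr = pd.DataFrame(
            {"flat": np.full(n, 3.0), "noise": rng.normal(size=n)}, index=pol.index
        )
        res = gene_trends(expr, pol)
        assert res.loc["flat", "F"] == pytest.approx(0.0, abs=1e-8)

    def test_permuted_polarization_gives_uniform_pvalues(self, rng):
        n = 200
        pol = pd.Series(rng.uniform(-1, 1, n), index=[f"c{i}" for i in range(n)])
        expr = pd.DataFrame(
            rng.normal(size=(n, 60)),
            index=pol.index,
            columns=[f"g{j}" for j in range(60)],
        )
        res = gene_trends(expr, pol)
        assert kstest(res["p"], "uniform").pvalue > 0.01

    def test_constant_polarization_rejected(self, rng):
        pol = pd.Series(np.full(150, 0.5), index=[f"c{i}" for i in range(150)])
        expr = pd.DataFrame(rng.normal(size=(150, 3)), index=pol.index)
        with pytest.raises(ValueError, match="constant"):
            gene_trends(expr, pol)
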