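"""Data-driven myeloid polarization: clustering, rooted-MST pseudotime,
differentiation states, the M1/M2 division boundary, and gene trends.

Myeloid cells are clustered in a 2-D phenotype embedding with a Gaussian
mixture (component count by BIC).  A minimum spanning tree over cluster
centroids, rooted at the monocyte-dominated cluster, provides the
differentiation skeleton; each cell is orthogonally projected onto its
nearest tree edge and its pseudotime is the path length from the root
centroid to the projection point.  (The skeleton replaces principal
curves with the MST polyline — a deliberate simplification that preserves
the rooted-branching pseudotime semantics.)  A two-state Gaussian mixture
on average pseudotime separates undifferentiated from differentiated
cells; a smoothing-spline boundary through the undifferentiated cells
divides the M1-like from the M2-like side; and the signed polarization
score is the pseudotime with the boundary-side sign (positive = M2-like
side by convention, re-orientable by a marker score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class MyeloidClusters:
    """GMM cluster labels, centroids, and the rooted centroid MST."""

    labels: pd.Series
    centroids: np.ndarray
    tree: nx.Graph
    root: int
    K: int
    bic_trace: pd.Series


def cluster_and_mst(
    embedding: pd.DataFrame,
    monocyte_flags: pd.Series,
    K_range=range(2, 26),
    seed: int = 0,
) -> MyeloidClusters:
    """Cluster the myeloid embedding and build the monocyte-rooted MST.

    The mixture's component count is selected by BIC over ``K_range``; the
    MST is built over cluster centroids with Euclidean edge weights, and
    the root is the cluster with the highest fraction of monocyte-flagged
    cells.
    """
    from sklearn.mixture import GaussianMixture

    K_range = sorted(set(int(k) for k in K_range))
    if not K_range or K_range[-1] < 2:
        raise ValueError("K_range must allow at least 2 clusters (no tree otherwise)")
    flags = monocyte_flags.reindex(embedding.index).fillna(False).astype(bool)
    if not flags.any():
        raise ValueError("no monocyte-flagged cells: cannot root the tree")
    X = embedding.to_numpy(dtype=float)
    bics, models = {}, {}
    for K in K_range:
        if K >= len(X):
            continue
        gmm = GaussianMixture(
            n_components=K, covariance_type="full", n_init=3, random_state=seed
        ).fit(X)
        bics[K] = float(gmm.bic(X))
        models[K] = gmm
    K_best = min(bics, key=lambda k: (bics[k], k))
    gmm = models[K_best]
    labels = pd.Series(gmm.predict(X), index=embedding.index, name="cluster")
    centroids = np.vstack(
        [X[labels.to_numpy() == k].mean(axis=0) for k in range(K_best)]
    )
    g = nx.Graph()
    for i in range(K_best):
        g.add_node(i)
        for j in range(i + 1, K_best):
            g.add_edge(i, j, weight=float(np.linalg.norm(centroids[i] - centroids[j])))
    tree = nx.minimum_spanning_tree(g, weight="weight")
    frac = labels.groupby(labels).apply(
        lambda s: flags.loc[s.index].mean()
    )
    root = int(frac.idxmax())
    return MyeloidClusters(
        labels=labels,
        centroids=centroids,
        tree=tree,
        root=root,
        K=K_best,
        bic_trace=pd.Series(bics, name="bic"),
    )


def _rooted_edges(clusters: MyeloidClusters):
    """Edges as (parent, child) with path length from root to parent."""
    tree, root, cent = clusters.tree, clusters.root, clusters.centroids
    depth = {root: 0.0}
    edges = []
    for parent, child in nx.bfs_edges(tree, root):
        length = tree.edges[parent, child]["weight"]
        depth[child] = depth[parent] + length
        edges.append((parent, child, depth[parent], length))
    leaves = [n for n in tree.nodes if tree.degree(n) == 1 and n != root]
    if not leaves:  # a single-edge tree rooted at one end
        leaves = [n for n in tree.nodes if n != root]
    lineages = {leaf: nx.shortest_path(tree, root, leaf) for leaf in leaves}
    return edges, lineages


def project_pseudotime(
    coords: pd.DataFrame, clusters: MyeloidClusters
) -> pd.DataFrame:
    """Orthogonally project cells onto the rooted MST polyline.

    Each cell is projected onto every tree edge segment (projection
    parameter clipped to the segment) and assigned to the nearest one;
    pseudotime is the root-to-projection arc length.  Per-lineage values
    exist for every root-to-leaf path through the projected edge and all
    coincide with the arc length, so the average pseudotime equals it; the
    number of lineages through the cell's edge is reported alongside.
    """
    X = coords.to_numpy(dtype=float)
    edges, lineages = _rooted_edges(clusters)
    cent = clusters.centroids
    best_d = np.full(len(X), np.inf)
    best_pt = np.zeros(len(X))
    best_edge = np.zeros(len(X), dtype=int)
    for ei, (parent, child, depth_parent, length) in enumerate(edges):
        a, b = cent[parent], cent[child]
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((X - a[None, :]) @ ab) / denom, 0.0, 1.0)
        proj = a[None, :] + t[:, None] * ab[None, :]
        d = np.linalg.norm(X - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_pt[better] = depth_parent + t[better] * length
        best_edge[better] = ei
    n_lineages = np.empty(len(X), dtype=int)
    for ei, (parent, child, _, _) in enumerate(edges):
        count = sum(
            1
            for path in lineages.values()
            if any(
                (path[i] == parent and path[i + 1] == child)
                or (path[i] == child and path[i + 1] == parent)
                for i in range(len(path) - 1)
            )
        )
        n_lineages[best_edge == ei] = max(count, 1)
    return pd.DataFrame(
        {
            "pseudotime": best_pt,
            "edge": best_edge,
            "distance_to_tree": best_d,
            "n_lineages": n_lineages,
        },
        index=coords.index,
    )


def classify_differentiation(avg_pseudotime: pd.Series, seed: int = 0) -> pd.Series:
    """Two-state Gaussian mixture on average pseudotime.

    The component with the larger mean is the differentiated state
    (unequal variances).  If a one-component model is preferred by BIC, or
    the pseudotimes are degenerate, every cell is undifferentiated and a
    warning is issued.
    """
    from sklearn.mixture import GaussianMixture

    pt = avg_pseudotime.to_numpy(dtype=float)
    if len(pt) < 30:
        raise ValueError(f"need >= 30 cells, got {len(pt)}")
    out = pd.Series("undifferentiated", index=avg_pseudotime.index, name="state", dtype=object)
    if np.allclose(pt, pt[0]):
        warnings.warn("all pseudotimes identical: single undifferentiated state")
        return out
    X = pt[:, None]
    g1 = GaussianMixture(n_components=1, random_state=seed).fit(X)
    g2 = GaussianMixture(n_components=2, n_init=5, random_state=seed).fit(X)
    if g1.bic(X) <= g2.bic(X):
        warnings.warn("BIC prefers one pseudotime state: all cells undifferentiated")
        return out
    comp = g2.predict(X)
    differentiated = int(np.argmax(g2.means_.ravel()))
    out[comp == differentiated] = "differentiated"
    return out


class DivisionBoundary:
    """Smooth curve axis2 = b(axis1) splitting M1- from M2-like cells.

    A cubic smoothing spline with GCV-selected penalty, clamped to its
    endpoint values outside the fitted axis-1 range.
    """

    def __init__(self, spline, x_min: float, x_max: float):
        self._spline = spline
        self.x_min = float(x_min)
        self.x_max = float(x_max)

    def __call__(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        return np.asarray(self._spline(x), dtype=float)


def fit_division_boundary(coords: pd.DataFrame) -> DivisionBoundary:
    """Fit the M1/M2 division boundary through undifferentiated cells."""
    from scipy.interpolate import make_smoothing_spline

    if len(coords) < 50:
        raise ValueError(f"need >= 50 undifferentiated cells, got {len(coords)}")
    x = coords.iloc[:, 0].to_numpy(dtype=float)
    y = coords.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # smoothing splines need strictly increasing abscissae
    xu, start = np.unique(x, return_index=True)
    if len(xu) < len(x):
        yu = np.array([y[x == v].mean() for v in xu])
    else:
        yu = y
    if len(xu) < 5:
        # essentially vertical data: constant boundary at the mean height
        class _Const:
            def __init__(self, c):
                self.c = c

            def __call__(self, x):
                return np.full_like(np.asarray(x, dtype=float), self.c)

        return DivisionBoundary(_Const(float(yu.mean())), xu.min(), xu.max())
    spline = make_smoothing_spline(xu, yu)  # lam chosen by GCV
    return DivisionBoundary(spline, xu.min(), xu.max())


def polarization_score(
    coords: pd.DataFrame,
    avg_pseudotime: pd.Series,
    boundary: DivisionBoundary,
    m2_scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Signed polarization: boundary-side sign times average pseudotime.

    score = sign(axis2 - b(axis1)) * pseudotime, with the positive side
    the M2-like side.  If ``m2_scores`` (a per-cell M2 marker score) is
    supplied and the negative side has the higher mean marker score, the
    orientation is flipped so that positive stays M2-like.  Cells with a
    score below the cohort mean are labeled M1-like, the others M2-like.
    """
    x = coords.iloc[:, 0].to_numpy(dtype=float)
    y = coords.iloc[:, 1].to_numpy(dtype=float)
    side = np.sign(y - boundary(x))
    if m2_scores is not None:
        s = m2_scores.reindex(coords.index).to_numpy(dtype=float)
        pos, neg = s[side > 0], s[side < 0]
        if len(pos) and len(neg) and np.nanmean(neg) > np.nanmean(pos):
            side = -side
    score = side * avg_pseudotime.reindex(coords.index).to_numpy(dtype=float)
    label = np.where(score < score.mean(), "M1", "M2")
    return pd.DataFrame(
        {"polarization": score, "side": side, "m1m2": label}, index=coords.index
    )


def m1_fraction_per_sample(m1m2: pd.Series, samples: pd.Series) -> pd.Series:
    """Per-sample macrophage M1 proportion M1 / (M1 + M2)."""
    df = pd.DataFrame({"label": m1m2, "sample": samples.reindex(m1m2.index)})
    return df.groupby("sample")["label"].apply(lambda s: float((s == "M1").mean()))


def _bspline_design(x: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline design matrix with ``df`` basis functions."""
    from scipy.interpolate import BSpline

    k = 3
    n_interior = df - k - 1
    if n_interior > 0:
        interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
    else:
        interior = np.array([])
    lo, hi = x.min(), x.max()
    t = np.r_[[lo] * (k + 1), interior, [hi] * (k + 1)]
    return BSpline.design_matrix(np.clip(x, lo, hi), t, k).toarray()


def gene_trends(
    expression: pd.DataFrame,
    polarization: pd.Series,
    df: int = 6,
    top_n: int = 40,
) -> pd.DataFrame:
    """Rank genes by smooth-trend association with polarization.

    Per gene, expression is regressed on a cubic spline basis of the
    polarization score and tested against the constant model with an F
    test; genes are ranked by F (largest first).  ``direction`` is the
    sign of the linear association, so the top genes per direction give
    the transcriptional programs of increasing and decreasing
    polarization.
    """
    pol = polarization.reindex(expression.index).to_numpy(dtype=float)
    if len(pol) < 100:
        raise ValueError("need >= 100 cells for trend ranking")
    if np.allclose(pol, pol[0]):
        raise ValueError("polarization is constant: trends undefined")
    from scipy import stats

    X = _bspline_design(pol, df)
    X = np.column_stack([np.ones(len(pol)), X[:, 1:]])  # absorb intercept
    Y = expression.to_numpy(dtype=float)
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    df_num = p - 1
    df_den = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    F = np.where(np.isfinite(F) & (F > 0), F, 0.0)
    pvals = stats.f.sf(F, df_num, df_den)
    centered = pol - pol.mean()
    denom = np.sqrt((centered**2).sum()) * np.sqrt(((Y - Y.mean(axis=0)) ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (centered @ (Y - Y.mean(axis=0))) / denom
    r = np.where(np.isfinite(r), r, 0.0)
    out = pd.DataFrame(
        {
            "F": F,
            "p": pvals,
            "direction": np.where(r >= 0, "increasing", "decreasing"),
        },
        index=expression.columns,
    )
    out["rank"] = out["F"].rank(ascending=False, method="first").astype(int)
    out = out.sort_values("rank")
    out["top"] = False
    for direction in ("increasing", "decreasing"):
        idx = out.index[out["direction"] == direction][:top_n]
        out.loc[idx, "top"] = True
    return out
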