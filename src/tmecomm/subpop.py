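"""Resolving broad cell types into phenotypically coherent subpopulations.

Each broad cell type is embedded into a low-dimensional phenotype space
(from per-cell pathway scores when available, otherwise principal axes of
log1p expression), the intrinsic dimensionality is estimated with a
packing-number (capacity dimension) estimator, and the embedding is cut
into equal-width grid bins per axis.  Bins with fewer than ``min_cells``
cells cohort-wide are merged into their nearest neighbor until every
subpopulation is adequately supported.  Subpopulation proportions within
each sample (P-hat) are the weights of the communication model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


def estimate_intrinsic_dimension(
    points: np.ndarray,
    radii: tuple[float, float],
    n_orders: int = 10,
    seed: int = 0,
) -> float:
    """Capacity-dimension estimate from greedy packing counts.

    A greedy r-packing keeps a point only if it lies at distance >= r from
    every point already kept; the packing number M(r) is the kept count.
    The capacity dimension is estimated as

        d = -(log M(r2) - log M(r1)) / (log r2 - log r1),   r1 < r2.

    The greedy count depends on visit order, so counts are averaged over
    ``n_orders`` random orderings (seeded).  Downstream embeddings use
    round(d) clipped to [1, 5].
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    r1, r2 = radii
    if not (0 < r1 < r2):
        raise ValueError("radii must satisfy 0 < r1 < r2")
    if np.allclose(pts, pts[0]):
        raise ValueError("all points identical: zero diameter point set")
    rng = np.random.default_rng(seed)
    counts = {r1: [], r2: []}
    for _ in range(n_orders):
        order = rng.permutation(len(pts))
        for r in (r1, r2):
            counts[r].append(_greedy_packing_count(pts[order], r))
    m1 = float(np.mean(counts[r1]))
    m2 = float(np.mean(counts[r2]))
    return -(np.log(m2) - np.log(m1)) / (np.log(r2) - np.log(r1))


def _greedy_packing_count(pts: np.ndarray, r: float) -> int:
    centers = np.empty((0, pts.shape[1]))
    # grow in chunks to keep the distance computations vectorized
    kept: list[np.ndarray] = []
    for p in pts:
        if not kept:
            kept.append(p)
            continue
        centers = np.asarray(kept)
        if np.min(np.linalg.norm(centers - p[None, :], axis=1)) >= r:
            kept.append(p)
    return len(kept)


@dataclass
class PhenotypeEmbedding:
    """Low-dimensional phenotype coordinates for the cells of one type."""

    coords: pd.DataFrame  # cells x dims, indexed by barcode
    cell_type: str
    seed: int
    method: str = "umap"

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def embed_phenotypes(
    scores: pd.DataFrame,
    cell_type: str,
    out_dims: int,
    seed: int = 0,
    method: str = "umap",
    n_neighbors: int = 15,
) -> PhenotypeEmbedding:
    """Embed one cell type's phenotype scores into ``out_dims`` dimensions.

    ``scores`` is a cells x pathways table (ssGSEA-like scores consumed as
    given, or the log1p-expression fallback prepared by the caller).
    ``method`` is ``"umap"`` (default, matches the reference analysis) or
    ``"pca"`` (fast deterministic alternative for large benchmark sweeps).
    """
    if out_dims < 1:
        raise ValueError("out_dims must be >= 1")
    if len(scores) < 50:
        raise ValueError(f"need >= 50 cells of type {cell_type!r}, got {len(scores)}")
    X = scores.to_numpy(dtype=float)
    if method == "umap":
        if len(scores) <= n_neighbors:
            raise ValueError("fewer cells than the UMAP neighborhood size")
        import umap

        reducer = umap.UMAP(
            n_components=out_dims, n_neighbors=n_neighbors, random_state=seed
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*n_jobs value.*random_state.*")
            emb = reducer.fit_transform(X)
    elif method == "pca":
        from sklearn.decomposition import PCA

        out_dims = min(out_dims, X.shape[1], X.shape[0])
        emb = PCA(n_components=out_dims, svd_solver="full", random_state=seed).fit_transform(X)
        # deterministic sign convention: orient each axis so its largest
        # absolute loading on the data is positive
        for j in range(emb.shape[1]):
            i = np.argmax(np.abs(emb[:, j]))
            if emb[i, j] < 0:
                emb[:, j] = -emb[:, j]
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    coords = pd.DataFrame(
        emb, index=scores.index, columns=[f"axis{i + 1}" for i in range(emb.shape[1])]
    )
    return PhenotypeEmbedding(coords=coords, cell_type=cell_type, seed=seed, method=method)


@dataclass
class SubpopulationPartition:
    """Per-cell subtype assignment and per-sample subtype proportions P-hat.

    ``labels`` maps barcode -> subtype name (``"<cell_type>|s<j>"``);
    ``subtype_celltype`` maps subtype -> broad cell type; ``proportions``
    is a samples x subtypes table whose rows sum to 1 over all subtypes of
    all cell types present in the sample.
    """

    labels: pd.Series
    subtype_celltype: pd.Series
    proportions: pd.DataFrame
    bin_info: dict = field(default_factory=dict)

    def subtypes_of(self, cell_type: str) -> list[str]:
        return list(self.subtype_celltype.index[self.subtype_celltype == cell_type])


def bin_subpopulations(
    embedding: PhenotypeEmbedding,
    samples: pd.Series,
    min_cells: int = 30,
    intervals_per_axis: int = 4,
) -> tuple[pd.Series, dict]:
    """Grid-bin one cell type's embedding into subpopulations.

    Every axis range is divided into ``intervals_per_axis`` equal-width
    intervals; cells fall into the product-grid cell containing them.
    Grid cells with fewer than ``min_cells`` cells cohort-wide are merged,
    sparsest first, into the nearest occupied bin by centroid distance
    until all subpopulations are adequately supported.  Subtype names are
    ordered by bin centroid along the first axis, so on a 1-D phenotype
    gradient the subtype index tracks the latent order.

    Returns per-cell subtype labels and a bin-boundary description.
    """
    if intervals_per_axis < 1:
        raise ValueError("intervals_per_axis must be >= 1")
    coords = embedding.coords.to_numpy(dtype=float)
    n, d = coords.shape
    ct = embedding.cell_type
    if n < min_cells:
        warnings.warn(
            f"cell type {ct!r} has only {n} cells cohort-wide; using a single subtype"
        )
        labels = pd.Series(f"{ct}|s1", index=embedding.coords.index, name="subtype")
        return labels, {"cell_type": ct, "edges": None, "n_bins": 1}

    edges = []
    digit = np.zeros((n, d), dtype=int)
    for j in range(d):
        lo, hi = coords[:, j].min(), coords[:, j].max()
        if hi <= lo:
            e = np.array([lo, lo + 1.0])
        else:
            e = np.linspace(lo, hi, intervals_per_axis + 1)
        edges.append(e)
        digit[:, j] = np.clip(np.searchsorted(e, coords[:, j], side="right") - 1, 0, len(e) - 2)

    # bin id per cell = tuple of interval indices; merge sparse bins
    keys = [tuple(row) for row in digit]
    assign = pd.Series(keys, index=embedding.coords.index)
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    bins = {k: np.array(v) for k, v in groups.items()}

    def centroid(idx: np.ndarray) -> np.ndarray:
        return coords[idx].mean(axis=0)

    while len(bins) > 1:
        sizes = {k: len(v) for k, v in bins.items()}
        small = [k for k, s in sizes.items() if s < min_cells]
        if not small:
            break
        k_small = min(small, key=lambda k: (sizes[k], k))
        cents = {k: centroid(v) for k, v in bins.items()}
        others = [k for k in bins if k != k_small]
        target = min(
            others, key=lambda k: (float(np.linalg.norm(cents[k] - cents[k_small])), k)
        )
        merged = np.concatenate([bins.pop(k_small), bins.pop(target)])
        # keep the target's key so merge chains stay stable
        bins[target] = np.sort(merged)

    order = sorted(bins, key=lambda k: (float(centroid(bins[k])[0]), k))
    labels = pd.Series("", index=embedding.coords.index, name="subtype", dtype=object)
    for rank, k in enumerate(order, start=1):
        labels.iloc[bins[k]] = f"{ct}|s{rank}"
    info = {
        "cell_type": ct,
        "edges": [e.tolist() for e in edges],
        "n_bins": len(bins),
        "min_cells": min_cells,
    }
    return labels, info


def partition_cohort(
    embeddings: dict[str, PhenotypeEmbedding],
    samples: pd.Series,
    min_cells: int = 30,
    intervals_per_axis: int = 4,
) -> SubpopulationPartition:
    """Bin every cell type and assemble per-sample subtype proportions.

    ``samples`` maps barcode -> sample for every cell in the cohort (cells
    of types without an embedding are ignored).  Proportions are computed
    per sample as subtype count / total partitioned cells in the sample,
    and therefore sum to 1 across all subtypes of all cell types.
    """
    all_labels = []
    subtype_ct = {}
    bin_info = {}
    for ct in sorted(embeddings):
        labels, info = bin_subpopulations(
            embeddings[ct], samples, min_cells=min_cells, intervals_per_axis=intervals_per_axis
        )
        all_labels.append(labels)
        bin_info[ct] = info
        for st in labels.unique():
            subtype_ct[st] = ct
    labels = pd.concat(all_labels)
    labels = labels.loc[[b for b in samples.index if b in labels.index]]
    tab = pd.crosstab(samples.loc[labels.index], labels)
    proportions = tab.div(tab.sum(axis=1), axis=0)
    proportions.index.name = "sample"
    return SubpopulationPartition(
        labels=labels,
        subtype_celltype=pd.Series(subtype_ct, name="cell_type"),
        proportions=proportions,
        bin_info=bin_info,
    )


def expression_phenotype_scores(dataset, cell_type: str, n_components: int = 10) -> pd.DataFrame:
    """log1p-expression fallback phenotype table for one cell type.

    Used when no ssGSEA-like phenotype-score matrix is supplied; flagged in
    the log so provenance is visible in pipeline reports.
    """
    mask = (dataset.obs["cell_type"] == cell_type).to_numpy()
    sub = dataset.matrix[mask]
    logger.info(
        "no phenotype scores supplied for %s: falling back to log1p expression axes",
        cell_type,
    )
    return pd.DataFrame(
        np.log1p(sub), index=dataset.obs.index[mask], columns=dataset.genes
    )
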