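"""Tumor-ecosystem composition: distances, archetypes, diversity.

Compositions are per-sample cell-type proportion vectors.  Similarity is
measured with the logit-Euclidean distance (Euclidean distance between
elementwise-logit-transformed proportions, after clamping away from 0 and
1), optionally supported by the Manhattan distance.  Archetypes are found
by embedding the compositions into two dimensions with UMAP and fitting a
Gaussian mixture whose component count is selected by BIC; new cohorts are
projected through the frozen embedding and classified by the frozen
mixture.

Note: UMAP fitted on logit-transformed coordinates with the Euclidean
metric is equivalent to UMAP on the precomputed pairwise logit-Euclidean
distance matrix, and — unlike the precomputed-distance mode — supports
projecting new samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

VALID_METRICS = ("logit-euclidean", "manhattan")


def _clamped_logit(comp: pd.DataFrame, eps: float) -> np.ndarray:
    if not (0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    p = np.clip(comp.to_numpy(dtype=float), eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def composition_from_metadata(obs: pd.DataFrame, level: str = "cell_type") -> pd.DataFrame:
    """Samples x cell-types proportion matrix from per-cell metadata."""
    tab = pd.crosstab(obs["sample"], obs[level])
    comp = tab.div(tab.sum(axis=1), axis=0)
    comp.index.name = "sample"
    return comp


def composition_distances(
    comp: pd.DataFrame, eps: float = 1e-3, metric: str = "logit-euclidean"
) -> pd.DataFrame:
    """Pairwise sample distances between compositions.

    ``logit-euclidean``: Euclidean distance between clamped-logit vectors.
    ``manhattan``: L1 distance between the raw proportion vectors (twice
    the total-variation distance between compositions).
    """
    if metric == "logit-euclidean":
        d = pdist(_clamped_logit(comp, eps), metric="euclidean")
    elif metric == "manhattan":
        d = pdist(comp.to_numpy(dtype=float), metric="cityblock")
    else:
        raise ValueError(f"unknown metric {metric!r}; use one of {VALID_METRICS}")
    return pd.DataFrame(squareform(d), index=comp.index, columns=comp.index)


def shannon_diversity(proportions) -> float:
    """Shannon entropy H = -sum p ln p over positive entries."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


@dataclass
class ArchetypeModel:
    """Frozen composition embedding + Gaussian mixture over archetypes."""

    umap_model: object
    gmm: object
    embedding: pd.DataFrame
    labels: pd.Series
    bic_trace: pd.Series
    K: int
    eps: float
    seed: int
    _train_logit: np.ndarray = field(repr=False, default=None)
    cell_types: list[str] = field(default_factory=list)

    def assign(self, comp: pd.DataFrame) -> pd.Series:
        """Classify new compositions with the frozen embedding + mixture.

        Rows numerically identical to a training composition keep their
        training label (projection of training points through the fitted
        UMAP transform is only approximate).
        """
        logit = _clamped_logit(comp[self.cell_types], self.eps)
        out = np.empty(len(comp), dtype=int)
        todo = []
        for i, row in enumerate(logit):
            match = np.flatnonzero(np.all(np.isclose(self._train_logit, row[None, :]), axis=1))
            if match.size:
                out[i] = int(self.labels.iloc[match[0]])
            else:
                todo.append(i)
        if todo:
            emb = self.umap_model.transform(logit[todo])
            out[np.asarray(todo)] = self.gmm.predict(emb)
        return pd.Series(out + 1, index=comp.index, name="archetype")


def fit_archetypes(
    comp: pd.DataFrame,
    K_range=range(1, 7),
    seed: int = 0,
    eps: float = 1e-3,
    n_neighbors: int = 15,
) -> ArchetypeModel:
    """Discover compositional archetypes by UMAP embedding + GMM/BIC.

    The 2-D embedding is trained on the training compositions only; a
    Gaussian mixture is fitted in embedding space for every candidate K
    and the minimum-BIC model is kept.  Labels are reported 1..K.
    """
    import umap
    from sklearn.mixture import GaussianMixture

    K_range = sorted(set(int(k) for k in K_range))
    if not K_range or K_range[0] < 1:
        raise ValueError("K_range must contain integers >= 1")
    n = len(comp)
    if K_range[-1] > n:
        raise ValueError(f"K_range maximum {K_range[-1]} exceeds sample count {n}")
    if n < 3 * K_range[-1]:
        raise ValueError("need >= 3 samples per candidate mixture component")
    logit = _clamped_logit(comp, eps)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        random_state=seed,
        min_dist=0.1,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs value.*random_state.*")
        emb = reducer.fit_transform(logit)
    bics = {}
    models = {}
    for K in K_range:
        gmm = GaussianMixture(
            n_components=K, covariance_type="full", n_init=5, random_state=seed
        ).fit(emb)
        bics[K] = float(gmm.bic(emb))
        models[K] = gmm
    K_best = min(bics, key=lambda k: (bics[k], k))
    gmm = models[K_best]
    labels = pd.Series(gmm.predict(emb), index=comp.index, name="archetype")
    return ArchetypeModel(
        umap_model=reducer,
        gmm=gmm,
        embedding=pd.DataFrame(emb, index=comp.index, columns=["umap1", "umap2"]),
        labels=labels,
        bic_trace=pd.Series(bics, name="bic"),
        K=K_best,
        eps=eps,
        seed=seed,
        _train_logit=logit,
        cell_types=list(comp.columns),
    )


def ward_linkage(distances: pd.DataFrame) -> np.ndarray:
    """Ward linkage on a precomputed composition distance matrix.

    Convenience for heatmap-style support views of the archetype
    structure.
    """
    from scipy.cluster.hierarchy import linkage

    return linkage(squareform(distances.to_numpy(), checks=False), method="ward")


def archetype_response_table(labels: pd.Series, response: pd.Series) -> dict:
    """Archetype x response contingency table with a chi-square summary.

    A simple convenience check of association between archetype membership
    and treatment response; not a substitute for a regression analysis of
    compositional effects.
    """
    from scipy.stats import chi2_contingency

    tab = pd.crosstab(labels, response.reindex(labels.index))
    chi2, p, dof, _ = chi2_contingency(tab)
    return {"table": tab, "chi2": float(chi2), "p": float(p), "dof": int(dof)}
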