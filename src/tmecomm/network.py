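"""Group contrasts of communication networks.

The central test shuffles tumor response labels (the tumor — not the
biopsy — is the exchangeable unit, so all samples of one patient move
together) and recomputes, for every directed cell-type pair, the
resistant-minus-sensitive difference in mean overall communication
strength C-bar.  The null distribution over shuffles yields a z statistic
and a rank-based p-value; Holm's step-down correction controls the
family-wise error over directed pairs.  Per-pathway differential tests
compare log(1 + C) per tumor between groups with BH-FDR control.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .communication import CommunicationTensor

logger = logging.getLogger(__name__)


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Holm step-down or Benjamini-Hochberg step-up adjusted p-values.

    Holm: running maximum of (m - k + 1) * p_(k), capped at 1.
    BH: running minimum (from the largest p down) of (m / k) * p_(k),
    capped at 1.  Original input order is restored.
    """
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    if method == "holm":
        scaled = (m - np.arange(m)) * ranked
        adj = np.minimum(np.maximum.accumulate(scaled), 1.0)
    elif method == "bh":
        scaled = ranked * m / (np.arange(m) + 1)
        adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    else:
        raise ValueError(f"unknown correction method {method!r}; use 'holm' or 'bh'")
    out = np.empty(m)
    out[order] = adj
    return out


def _tumor_table(cbar: pd.DataFrame, patients: pd.Series) -> pd.DataFrame:
    """Per-tumor mean C-bar for every directed pair (tumors x pairs)."""
    df = cbar.copy()
    df["patient"] = df["sample"].map(patients)
    if df["patient"].isna().any():
        missing = sorted(df.loc[df["patient"].isna(), "sample"].unique())
        raise ValueError(f"samples with no patient mapping: {missing}")
    wide = (
        df.groupby(["patient", "sender", "receiver"], observed=True)["cbar"]
        .mean()
        .unstack(["sender", "receiver"])
    )
    return wide


def bootstrap_network_test(
    cbar: pd.DataFrame,
    response: pd.Series,
    patients: pd.Series | None = None,
    B: int = 1000,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> pd.DataFrame:
    """Randomization contrast of C-bar networks between response groups.

    Parameters
    ----------
    cbar
        Long table with columns sample, sender, receiver, cbar (the
        summary layer of :func:`standardize_and_summarize`).
    response
        Tumor-level labels indexed by patient, values "resistant" /
        "sensitive".
    patients
        Map sample -> patient.  If omitted, samples are assumed to be the
        tumors themselves.
    B
        Number of label shuffles (the same shuffle is applied to every
        directed pair, preserving the network structure of the null).
    exhaustive
        Enumerate all distinct label assignments instead of sampling.
        ``None`` (default) auto-enables enumeration whenever the number of
        distinct assignments does not exceed ``B``.

    Returns
    -------
    DataFrame indexed by (sender, receiver) with observed difference
    (resistant minus sensitive), null mean/sd, z, rank p (add-one
    convention when sampling; exact rank among all assignments when
    enumerating) and Holm-adjusted p.
    """
    if patients is None:
        patients = pd.Series(
            {s: s for s in cbar["sample"].unique()}, name="patient"
        )
    wide = _tumor_table(cbar, patients)
    labels = response.reindex(wide.index)
    if labels.isna().any():
        missing = sorted(wide.index[labels.isna()])
        raise ValueError(f"tumors with no response label: {missing}")
    is_res = (labels == "resistant").to_numpy()
    n_res = int(is_res.sum())
    n_sen = int((~is_res).sum())
    if n_res < 2 or n_sen < 2:
        raise ValueError(
            f"need >= 2 tumors per group, got {n_res} resistant / {n_sen} sensitive"
        )
    M = wide.to_numpy(dtype=float)  # tumors x pairs (may contain NaN)
    n = M.shape[0]

    def group_diff(mask: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(M[mask], axis=0) - np.nanmean(M[~mask], axis=0)

    obs = group_diff(is_res)

    n_assign = comb(n, n_res)
    use_exhaustive = exhaustive if exhaustive is not None else n_assign <= B
    if not use_exhaustive and B < 100:
        warnings.warn(f"B={B} randomizations is low; p-values will be coarse")
    if use_exhaustive:
        null = np.empty((n_assign, M.shape[1]))
        for bi, idx in enumerate(combinations(range(n), n_res)):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            null[bi] = group_diff(mask)
        # exact rank p among all assignments; the observed assignment is
        # one of them, so p is never 0
        p = (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).mean(axis=0)
        B_eff = n_assign
    else:
        rng = np.random.default_rng(seed)
        null = np.empty((B, M.shape[1]))
        for bi in range(B):
            null[bi] = group_diff(rng.permutation(is_res))
        p = (1.0 + (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)) / (B + 1.0)
        B_eff = B

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (obs - null_mean) / null_sd, 0.0)

    result = pd.DataFrame(
        {
            "obs_diff": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
        },
        index=pd.MultiIndex.from_tuples(wide.columns, names=["sender", "receiver"]),
    )
    result["p_holm"] = adjust_pvalues(result["p"], "holm")
    result["B"] = B_eff
    result["seed"] = seed
    return result


def differential_lr_test(
    tensor: CommunicationTensor,
    response: pd.Series,
    patients: pd.Series | None = None,
    sender: str | None = None,
    receiver: str | None = None,
) -> pd.DataFrame:
    """Per-pathway two-group contrast of log(1 + C) for one directed pair.

    Per tumor (averaging a tumor's samples), the raw cell-type
    communication score is log1p-transformed and compared between
    resistant and sensitive tumors with a two-sample t test (the
    linear-model t on a group indicator).  BH-FDR is applied across the
    pathways of the (sender, receiver) family.  Pathways absent in every
    tumor are excluded and logged.
    """
    from scipy import stats

    raw = tensor.raw.sel(sender=sender, receiver=receiver)
    df = raw.to_dataframe(name="raw").reset_index()
    if patients is None:
        patients = pd.Series({s: s for s in df["sample"].unique()})
    df["patient"] = df["sample"].map(patients)
    per_tumor = (
        df.groupby(["patient", "pathway"], observed=True)["raw"].mean().unstack("pathway")
    )
    labels = response.reindex(per_tumor.index)
    is_res = (labels == "resistant").to_numpy()
    if is_res.sum() < 2 or (~is_res).sum() < 2:
        raise ValueError("need >= 2 tumors per group")
    rows = []
    for pathway in per_tumor.columns:
        vals = per_tumor[pathway]
        if vals.isna().all():
            logger.info("pathway %s absent in all tumors; excluded", pathway)
            continue
        lv = np.log1p(vals.to_numpy(dtype=float))
        a, b = lv[is_res], lv[~is_res]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            logger.info("pathway %s lacks per-group support; excluded", pathway)
            continue
        est = float(np.mean(a) - np.mean(b))
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"pathway": pathway, "est": est, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows).set_index("pathway")
    out["q"] = adjust_pvalues(out["p"], "bh") if len(out) else []
    out["sender"] = sender
    out["receiver"] = receiver
    return out


def export_network(summary: pd.DataFrame, weight_col: str = "weight") -> pd.DataFrame:
    """Directed weighted edge list with strong-edge flags.

    ``summary`` has columns sender, receiver and a weight column (e.g. a
    group's mean C-bar per pair).  An edge is strong iff its weight
    exceeds mean + 1 sd (n-1 denominator) over all edges of the graph;
    self-edges are permitted.
    """
    edges = summary.rename(columns={weight_col: "weight"})[["sender", "receiver", "weight"]].copy()
    w = edges["weight"].to_numpy(dtype=float)
    if len(w) >= 2 and np.nanstd(w, ddof=1) > 0:
        threshold = np.nanmean(w) + np.nanstd(w, ddof=1)
    else:
        threshold = np.inf
    edges["strong"] = edges["weight"] > threshold
    return edges


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Write an edge list from :func:`export_network` as GraphML."""
    import networkx as nx

    g = nx.DiGraph()
    for _, row in edges.iterrows():
        g.add_edge(
            str(row["sender"]), str(row["receiver"]),
            weight=float(row["weight"]), strong=bool(row["strong"]),
        )
    nx.write_graphml(g, path)
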