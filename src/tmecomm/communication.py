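"""Steady-state signaling model and tumor-wide communication scores.

The model tracks the concentration S of a ligand in the tumor
microenvironment:

    dS/dt = sum_i sigma * x_i * P_i  -  sum_j q_j * y_j * gamma * P_j * S  -  mu * S

with production proportional to each sender subpopulation's ligand
expression x_i and abundance P_i, removal by decay/diffusion (mu) and by
receptor binding with internalization (gamma, q_j).  At steady state

    S* = sigma * sum_i x_i P_i / (sum_j q_j y_j gamma P_j + mu)

and, assuming ligand release after receptor binding (q_j small), the signal
received by a cell of subpopulation j through pathway k is proportional to

    C_jk  ∝  y_jk * sum_i x_ik * P_i,

the tumor-wide communication score.  Reported scores drop the constant
gamma*sigma/mu (cross-sample standardization removes constants anyway);
``steady_state_signal`` retains the full constants for model work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .io import ExpressionDataset, LRDatabase
from .subpop import SubpopulationPartition

logger = logging.getLogger(__name__)


@dataclass
class SteadyStateParams:
    """Rates of the ligand balance model: release sigma, removal mu,
    receptor binding gamma, and per-receiver internalization rates q."""

    sigma: float = 1.0
    mu: float = 1.0
    gamma: float = 1.0
    q: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        if self.mu < 0 or self.sigma < 0 or self.gamma < 0 or np.any(self.q < 0):
            raise ValueError("rates must be non-negative")


def steady_state_signal(
    params: SteadyStateParams,
    x,
    P,
    y=None,
    P_recv=None,
) -> float:
    """Steady-state ligand concentration S*.

    With q = 0 this reduces to (sigma/mu) * sum_i x_i P_i.  Raises when the
    removal term is identically zero (no decay, no uptake): the steady
    state is then unbounded.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    P = np.atleast_1d(np.asarray(P, dtype=float))
    production = params.sigma * float(np.sum(x * P))
    uptake = 0.0
    if y is not None:
        y = np.atleast_1d(np.asarray(y, dtype=float))
        P_recv = np.atleast_1d(np.asarray(P_recv, dtype=float))
        q = np.broadcast_to(params.q, y.shape)
        uptake = float(np.sum(q * y * params.gamma * P_recv))
    denom = uptake + params.mu
    if denom <= 0:
        raise ValueError("mu = 0 with zero uptake: steady state is unbounded")
    return production / denom


def lr_comm_score(x_ik: float, y_jk: float, p_i: float) -> float:
    """Subpopulation-level communication: C_{i->j,k} = y_jk * x_ik * P_i."""
    if x_ik < 0 or y_jk < 0 or not (0 <= p_i <= 1):
        raise ValueError("expression must be >= 0 and the proportion in [0, 1]")
    return y_jk * x_ik * p_i


def tumor_wide_received(x, P, y_jk: float) -> float:
    """Tumor-wide signal received by one cell: y_jk * sum_i x_ik * P_i.

    ``x`` and ``P`` run over ALL subpopulations of all cell types present
    in the sample; restricting them to a single sender subpopulation
    recovers the classic single-pair ligand x receptor expression product
    (times P-hat).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    P = np.atleast_1d(np.asarray(P, dtype=float))
    if x.size == 0:
        raise ValueError("empty sample: no sender subpopulations")
    if y_jk < 0 or np.any(x < 0) or np.any(P < 0):
        raise ValueError("expression and proportions must be non-negative")
    return float(y_jk) * float(np.sum(x * P))


def celltype_comm(x_sender, P_sender, y_receiver, P_receiver) -> float | None:
    """Cell-type level communication via one pathway.

    Sums the tumor-wide score over the sender type's subpopulations and
    averages over the receiver type's subpopulations weighted by abundance:

        C_{s -> r-bar, k} = (sum_i x_i P_i) * (sum_z y_z P_z / sum_z P_z).

    Returns None (absent) when either side has no subpopulations present.
    """
    x = np.atleast_1d(np.asarray(x_sender, dtype=float))
    Ps = np.atleast_1d(np.asarray(P_sender, dtype=float))
    y = np.atleast_1d(np.asarray(y_receiver, dtype=float))
    Pr = np.atleast_1d(np.asarray(P_receiver, dtype=float))
    if x.size == 0 or y.size == 0 or float(Pr.sum()) == 0.0:
        return None
    sent = float(np.sum(x * Ps))
    recv = float(np.sum(y * Pr) / np.sum(Pr))
    return sent * recv


@dataclass
class CommunicationTensor:
    """Scores indexed by (sample, sender type, receiver type, pathway).

    ``raw`` holds non-negative scores with NaN marking pairs absent from a
    sample (missing sender or receiver type); ``standardized`` is filled by
    :func:`standardize_and_summarize` (per-pathway z-scores across
    samples), and ``cbar`` is the per-(sample, sender, receiver) median of
    standardized scores across pathways — the overall strength of
    communication between two cell types.
    """

    raw: xr.DataArray
    standardized: xr.DataArray | None = None
    cbar: pd.DataFrame | None = None
    sent_margin: pd.DataFrame | None = None
    received_margin: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.raw.coords["sample"].values]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (sample, sender, receiver, pathway, raw[, standardized])."""
        df = self.raw.to_dataframe(name="raw").reset_index()
        if self.standardized is not None:
            df["standardized"] = self.standardized.to_dataframe(name="s").reset_index()["s"]
        return df

    def write(self, path) -> None:
        from .io import FLOAT_FORMAT

        self.to_frame().to_csv(
            path, sep="\t", index=False, lineterminator="\n", float_format=FLOAT_FORMAT
        )


def compute_communication_tensor(
    dataset: ExpressionDataset,
    partition: SubpopulationPartition,
    lrdb: LRDatabase,
) -> CommunicationTensor:
    """Score every (sample, sender type, receiver type, pathway).

    Sender and receiver profiles are within-sample subpopulation mean CPM
    of the pathway's ligand and receptor genes; abundances are the
    partition's per-sample proportions P-hat.  Scores factor as
    S[sample, sender, k] * R[sample, receiver, k] with

        S = sum_{i in sender subpops} x_ik P_i
        R = sum_{z in receiver subpops} y_zk P_z / sum_z P_z,

    so the tensor is filled with two dense contractions per sample.
    """
    missing = [g for g in sorted(lrdb.genes) if g not in dataset.genes]
    if missing:
        raise ValueError(f"LR genes absent from dataset: {missing}")
    cell_types = sorted(partition.subtype_celltype.unique())
    pathways = lrdb.pathway_ids
    samples = sorted(partition.proportions.index)
    ligands = [lrdb[p].ligand for p in pathways]
    receptors = [lrdb[p].receptor for p in pathways]

    # subpopulation mean CPM per sample for all LR genes
    lr_genes = sorted(lrdb.genes)
    expr = dataset.expression_frame(lr_genes)
    cells = partition.labels.index
    frame = expr.loc[cells].copy()
    frame["subtype"] = partition.labels
    frame["sample"] = dataset.obs.loc[cells, "sample"]
    means = frame.groupby(["sample", "subtype"], observed=True)[lr_genes].mean()

    S = np.full((len(samples), len(cell_types), len(pathways)), np.nan)
    R = np.full_like(S, np.nan)
    prop = partition.proportions
    for si, sample in enumerate(samples):
        if sample not in means.index.get_level_values(0):
            continue
        m_s = means.loc[sample]
        p_s = prop.loc[sample]
        for ci, ct in enumerate(cell_types):
            subs = [
                st
                for st in partition.subtypes_of(ct)
                if st in m_s.index and p_s.get(st, 0.0) > 0
            ]
            if not subs:
                continue
            P = p_s[subs].to_numpy(dtype=float)
            X = m_s.loc[subs, ligands].to_numpy(dtype=float)  # subpops x pathways
            Y = m_s.loc[subs, receptors].to_numpy(dtype=float)
            S[si, ci, :] = P @ X
            R[si, ci, :] = (P @ Y) / P.sum()

    raw = S[:, :, None, :] * R[:, None, :, :]
    arr = xr.DataArray(
        raw,
        dims=("sample", "sender", "receiver", "pathway"),
        coords={
            "sample": samples,
            "sender": cell_types,
            "receiver": cell_types,
            "pathway": pathways,
        },
        name="communication",
    )
    return CommunicationTensor(
        raw=arr,
        provenance={"n_subtypes": int(partition.subtype_celltype.size), "n_pathways": len(pathways)},
    )


def standardize_and_summarize(tensor: CommunicationTensor) -> CommunicationTensor:
    """Standardize pathway scores across samples and summarize networks.

    Per (sender, receiver, pathway), scores are z-scored across samples
    (sample standard deviation, n-1 denominator); zero-variance pathways
    are set to 0.  The overall strength C-bar per (sample, sender,
    receiver) is the median of standardized scores across pathways with
    non-absent values.  Per-cell-type signal-sent and signal-received
    margins (mean C-bar over receivers resp. senders) are also emitted.
    """
    raw = tensor.raw
    if raw.sizes["sample"] < 2:
        raise ValueError("cannot standardize a single-sample tensor")
    mean = raw.mean(dim="sample", skipna=True)
    sd = raw.std(dim="sample", skipna=True, ddof=1)
    std = xr.where(sd > 0, (raw - mean) / sd, 0.0)
    std = std.where(raw.notnull())  # keep absences absent
    cbar = (
        std.median(dim="pathway", skipna=True)
        .to_dataframe(name="cbar")
        .reset_index()
    )
    sent = (
        cbar.groupby(["sample", "sender"], observed=True)["cbar"].mean().reset_index()
        .rename(columns={"cbar": "signal_sent"})
    )
    received = (
        cbar.groupby(["sample", "receiver"], observed=True)["cbar"].mean().reset_index()
        .rename(columns={"cbar": "signal_received"})
    )
    return CommunicationTensor(
        raw=raw,
        standardized=std,
        cbar=cbar,
        sent_margin=sent,
        received_margin=received,
        provenance=dict(tensor.provenance),
    )
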