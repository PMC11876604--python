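"""Config-driven end-to-end orchestration.

Stages, in order: cohort input (real files or the synthetic generator),
composition + archetypes, subpopulation partition, communication tensor
(raw + standardized), per-contrast network randomization tests and
per-pathway differential tables, network edge-list export, and (when
myeloid cells are present) the polarization pipeline.  Every artifact is
a TSV; a MANIFEST records seeds, parameters, and row counts so that two
runs with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .communication import compute_communication_tensor, standardize_and_summarize
from .composition import composition_from_metadata, fit_archetypes, shannon_diversity
from .io import FLOAT_FORMAT, ExpressionDataset, LRDatabase, read_lr_table
from .myeloid import (
    classify_differentiation,
    cluster_and_mst,
    fit_division_boundary,
    m1_fraction_per_sample,
    polarization_score,
    project_pseudotime,
)
from .network import bootstrap_network_test, differential_lr_test, export_network
from .subpop import embed_phenotypes, expression_phenotype_scores, partition_cohort
from .synthetic import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of ``synthetic`` or
    ``expression_dir`` must be given."""

    outdir: str | Path
    synthetic: CohortConfig | None = None
    expression_dir: str | Path | None = None
    lr_table: str | Path | None = None
    phenotype_scores: str | Path | None = None
    contrasts: list[dict] = field(default_factory=list)
    min_cells: int = 30
    intervals_per_axis: int = 4
    embed_method: str = "pca"
    embed_dims: int = 2
    B: int = 1000
    archetype_K_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    myeloid_K_range: tuple[int, ...] = tuple(range(2, 26))
    eps: float = 1e-3
    seed: int = 0
    monocyte_marker: str | None = "CD14"
    myeloid_cell_type: str = "Myeloid"
    run_archetypes: bool = True
    run_myeloid: bool = True
    make_plots: bool = False

    def validate(self) -> None:
        if (self.synthetic is None) == (self.expression_dir is None):
            raise ValueError("specify exactly one of synthetic config or expression_dir")
        if self.expression_dir is not None and self.lr_table is None:
            raise ValueError("real-input mode requires an lr_table path")


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format=FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis chain and return the artifact directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    # ------------------------------------------------------------ input
    if config.synthetic is not None:
        dataset, truth = simulate_cohort(config.synthetic)
        lrdb = config.synthetic.lr_database()
        dataset.write_dir(outdir / "cohort")
        _write(truth.samples.reset_index(), outdir / "truth_samples.tsv")
        _write(truth.planted, outdir / "truth_planted.tsv")
        manifest["input"] = {"mode": "synthetic", "seed": config.synthetic.seed}
    else:
        dataset = ExpressionDataset.read_dir(config.expression_dir)
        lrdb = read_lr_table(config.lr_table)
        manifest["input"] = {"mode": "files", "expression_dir": str(config.expression_dir)}
    logger.info("input: %d cells, %d genes, %d samples", dataset.n_cells, len(dataset.genes), len(dataset.samples))
    manifest["stages"]["input"] = {"cells": dataset.n_cells, "samples": len(dataset.samples)}

    # ----------------------------------------------------- composition
    comp = composition_from_metadata(dataset.obs)
    comp_out = comp.copy()
    comp_out["shannon_diversity"] = [shannon_diversity(row) for _, row in comp.iterrows()]
    _write(comp_out.reset_index(), outdir / "composition.tsv")
    if config.run_archetypes and len(comp) >= 3 * max(config.archetype_K_range):
        model = fit_archetypes(
            comp, K_range=config.archetype_K_range, seed=config.seed, eps=config.eps
        )
        arch = model.embedding.copy()
        arch["archetype"] = model.labels + 1
        _write(arch.reset_index().rename(columns={"index": "sample"}), outdir / "archetypes.tsv")
        _write(model.bic_trace.rename_axis("K").reset_index(), outdir / "archetype_bic.tsv")
        manifest["stages"]["archetypes"] = {"K": model.K}
    else:
        manifest["stages"]["archetypes"] = {"skipped": True}

    # -------------------------------------------------------- partition
    phenotype = None
    if config.phenotype_scores is not None:
        phenotype = pd.read_csv(config.phenotype_scores, sep="\t", index_col=0)
    embeddings = {}
    for ct in sorted(dataset.obs["cell_type"].unique()):
        mask = dataset.obs["cell_type"] == ct
        if mask.sum() < 50:
            logger.info("cell type %s has < 50 cells; skipped from partition", ct)
            continue
        if phenotype is not None:
            scores = phenotype.loc[dataset.obs.index[mask]]
        else:
            scores = expression_phenotype_scores(dataset, ct)
        embeddings[ct] = embed_phenotypes(
            scores, ct, out_dims=config.embed_dims, seed=config.seed, method=config.embed_method
        )
    partition = partition_cohort(
        embeddings,
        dataset.obs["sample"],
        min_cells=config.min_cells,
        intervals_per_axis=config.intervals_per_axis,
    )
    part_out = pd.DataFrame(
        {
            "barcode": partition.labels.index,
            "cell_type": partition.labels.map(partition.subtype_celltype),
            "subtype": partition.labels.values,
            "sample": dataset.obs.loc[partition.labels.index, "sample"].values,
        }
    )
    _write(part_out, outdir / "partition.tsv")
    manifest["stages"]["partition"] = {"n_subtypes": int(partition.subtype_celltype.size)}

    # ---------------------------------------------------- communication
    tensor = standardize_and_summarize(
        compute_communication_tensor(dataset, partition, lrdb)
    )
    tensor.write(outdir / "communication_tensor.tsv")
    _write(tensor.cbar, outdir / "cbar.tsv")
    _write(tensor.sent_margin, outdir / "signal_sent.tsv")
    _write(tensor.received_margin, outdir / "signal_received.tsv")
    manifest["stages"]["communication"] = {"n_pathways": len(lrdb)}

    # -------------------------------------------------------- contrasts
    sample_meta = dataset.obs.groupby("sample")[["patient", "day", "treatment", "response"]].first()
    contrasts = config.contrasts or [
        {"treatment": t, "day": int(d)}
        for t in sorted(sample_meta["treatment"].unique())
        for d in sorted(sample_meta["day"].unique())
    ]
    response = sample_meta.groupby("patient")["response"].first()
    cell_types = sorted(partition.subtype_celltype.unique())
    for ci, contrast in enumerate(contrasts):
        sel = sample_meta[
            (sample_meta["treatment"] == contrast["treatment"])
            & (sample_meta["day"] == contrast["day"])
        ]
        tag = f"{contrast['treatment']}_d{contrast['day']}"
        groups = response.reindex(sel["patient"].unique()).value_counts()
        if groups.get("resistant", 0) < 2 or groups.get("sensitive", 0) < 2:
            raise ValueError(f"contrast {tag}: a response group is empty or too small")
        cbar_sel = tensor.cbar[tensor.cbar["sample"].isin(sel.index)]
        res = bootstrap_network_test(
            cbar_sel,
            response,
            patients=sample_meta["patient"],
            B=config.B,
            seed=config.seed + 1000 + ci,
        )
        _write(res.reset_index(), outdir / f"network_test_{tag}.tsv")
        diff_tables = []
        for s in cell_types:
            for r in cell_types:
                try:
                    d = differential_lr_test(
                        _subset_tensor(tensor, sel.index),
                        response,
                        patients=sample_meta["patient"],
                        sender=s,
                        receiver=r,
                    )
                except ValueError:
                    continue
                diff_tables.append(d.reset_index())
        if diff_tables:
            _write(pd.concat(diff_tables, ignore_index=True), outdir / f"differential_lr_{tag}.tsv")
        for group in ("resistant", "sensitive"):
            tumors = response[response == group].index
            g_samples = sel[sel["patient"].isin(tumors)].index
            mean_net = (
                cbar_sel[cbar_sel["sample"].isin(g_samples)]
                .groupby(["sender", "receiver"], observed=True)["cbar"]
                .mean()
                .reset_index()
                .rename(columns={"cbar": "weight"})
            )
            _write(export_network(mean_net), outdir / f"network_{tag}_{group}.tsv")
        manifest["stages"][f"contrast_{tag}"] = {"pairs": int(len(res))}

    # ---------------------------------------------------------- myeloid
    if config.run_myeloid:
        _run_myeloid_stage(config, dataset, outdir, manifest)

    if config.make_plots:
        _make_plots(outdir)

    manifest["package"] = "tmecomm"
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def _subset_tensor(tensor, samples):
    from .communication import CommunicationTensor

    return CommunicationTensor(raw=tensor.raw.sel(sample=sorted(samples)))


def _make_plots(outdir: Path) -> None:
    """Quick-look figures: C-bar network heatmaps and, when present, the
    archetype embedding and myeloid polarization map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = outdir / "plots"
    plots.mkdir(exist_ok=True)
    cbar = pd.read_csv(outdir / "cbar.tsv", sep="\t")
    mat = cbar.groupby(["sender", "receiver"], observed=True)["cbar"].mean().unstack()
    fig, ax = plt.subplots(figsize=(4, 3.2))
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(mat.index)), mat.index)
    ax.set_xlabel("receiver")
    ax.set_ylabel("sender")
    fig.colorbar(im, label="mean standardized communication")
    fig.tight_layout()
    fig.savefig(plots / "cbar_network.png", dpi=150)
    plt.close(fig)
    arch_path = outdir / "archetypes.tsv"
    if arch_path.exists():
        arch = pd.read_csv(arch_path, sep="\t")
        fig, ax = plt.subplots(figsize=(3.6, 3.2))
        for k, grp in arch.groupby("archetype"):
            ax.scatter(grp["umap1"], grp["umap2"], s=16, label=f"archetype {k}")
        ax.legend(fontsize=7)
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        fig.tight_layout()
        fig.savefig(plots / "archetypes.png", dpi=150)
        plt.close(fig)
    mye_path = outdir / "myeloid.tsv"
    if mye_path.exists():
        mye = pd.read_csv(mye_path, sep="\t")
        if "polarization" in mye.columns:
            fig, ax = plt.subplots(figsize=(3.8, 3.2))
            sc = ax.scatter(
                mye["axis1"], mye["axis2"], c=mye["polarization"], s=6, cmap="coolwarm"
            )
            fig.colorbar(sc, label="polarization (+ = M2-like)")
            ax.set_xlabel("axis 1")
            ax.set_ylabel("axis 2")
            fig.tight_layout()
            fig.savefig(plots / "myeloid_polarization.png", dpi=150)
            plt.close(fig)


def _run_myeloid_stage(config, dataset, outdir: Path, manifest: dict) -> None:
    mask = dataset.obs["cell_type"] == config.myeloid_cell_type
    if mask.sum() < 100:
        manifest["stages"]["myeloid"] = {"skipped": True, "n_cells": int(mask.sum())}
        return
    scores = expression_phenotype_scores(dataset, config.myeloid_cell_type)
    emb = embed_phenotypes(
        scores, config.myeloid_cell_type, out_dims=2, seed=config.seed, method=config.embed_method
    )
    if config.monocyte_marker and config.monocyte_marker in dataset.genes:
        marker = dataset.expression_frame([config.monocyte_marker]).loc[emb.coords.index].iloc[:, 0]
        flags = marker > marker.median()
    else:
        # fall back to rooting at the densest end of the first axis
        flags = emb.coords.iloc[:, 0] < emb.coords.iloc[:, 0].quantile(0.1)
    K_range = [k for k in config.myeloid_K_range if k < mask.sum()]
    clusters = cluster_and_mst(emb.coords, flags, K_range=K_range, seed=config.seed)
    pt = project_pseudotime(emb.coords, clusters)
    state = classify_differentiation(pt["pseudotime"], seed=config.seed)
    undiff = emb.coords[state == "undifferentiated"]
    if len(undiff) >= 50:
        boundary = fit_division_boundary(undiff)
        pol = polarization_score(emb.coords, pt["pseudotime"], boundary)
        out = pd.concat([emb.coords, pt[["pseudotime"]], state, pol[["polarization", "m1m2"]]], axis=1)
        m1 = m1_fraction_per_sample(pol["m1m2"], dataset.obs["sample"])
        _write(m1.rename("m1_fraction").reset_index(), outdir / "myeloid_m1_fraction.tsv")
    else:
        out = pd.concat([emb.coords, pt[["pseudotime"]], state], axis=1)
    out.insert(0, "cluster", clusters.labels)
    _write(out.rename_axis("barcode").reset_index(), outdir / "myeloid.tsv")
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "length": clusters.tree.edges[u, v]["weight"]}
            for u, v in sorted(clusters.tree.edges)
        ]
    )
    _write(edges, outdir / "myeloid_tree.tsv")
    manifest["stages"]["myeloid"] = {"K": clusters.K, "root": clusters.root}
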