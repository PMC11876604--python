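"""Benchmark experiments on synthetic cohorts with known ground truth.

These are the package's study-condition experiments: permutation-test
calibration on null cohorts, detection power for a planted cancer->myeloid
ligand effect, compositional archetype recovery, and myeloid polarization
recovery.  Problem sizes are desk-scale (hundreds of cells per sample,
tens of tumors) so every experiment runs in seconds to a few minutes on
one CPU; the planted-effect structure follows the benchmark cohort
profile in :mod:`tmecomm.synthetic`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import (
    bootstrap_network_test,
    compute_communication_tensor,
    differential_lr_test,
    embed_phenotypes,
    partition_cohort,
    simulate_cohort,
    standardize_and_summarize,
)
from .subpop import expression_phenotype_scores
from .synthetic import PlantedEffect, benchmark_cohort_config

FOCAL_PAIR = ("Cancer", "Myeloid")
PLANTED_PATHWAYS = ["IL15_IL15RA", "IL15_IL2RB"]


def score_cohort(dataset, lrdb, seed: int = 0):
    """Partition (log1p-PCA phenotype axes) and score one cohort."""
    embeddings = {
        ct: embed_phenotypes(
            expression_phenotype_scores(dataset, ct), ct, out_dims=2, seed=seed, method="pca"
        )
        for ct in sorted(dataset.obs["cell_type"].unique())
    }
    partition = partition_cohort(embeddings, dataset.obs["sample"])
    tensor = standardize_and_summarize(
        compute_communication_tensor(dataset, partition, lrdb)
    )
    return partition, tensor


def planted_ligand_sd(seed: int = 0, n_patients_per_group: int = 10, n_cells: int = 300) -> float:
    """One cohort-sd of the planted ligand: sd of IL15 CPM across cancer
    cells of a null pilot cohort (the unit of the planted effect size)."""
    cfg = benchmark_cohort_config(
        n_patients_per_group=n_patients_per_group, n_cells_per_sample=n_cells, seed=seed
    )
    ds, _ = simulate_cohort(cfg)
    il15 = ds.expression_frame(["IL15"]).iloc[:, 0]
    return float(il15[ds.obs["cell_type"] == "Cancer"].std(ddof=1))


def null_network_pvalue(
    seed: int,
    n_patients_per_group: int = 5,
    n_cells: int = 150,
    B: int = 199,
) -> float:
    """Unadjusted permutation p for the focal pair on one null cohort."""
    cfg = benchmark_cohort_config(
        n_patients_per_group=n_patients_per_group, n_cells_per_sample=n_cells, seed=seed
    )
    ds, _ = simulate_cohort(cfg)
    _, tensor = score_cohort(ds, cfg.lr_database())
    response = ds.obs.groupby("patient")["response"].first()
    patients = ds.obs.groupby("sample")["patient"].first()
    res = bootstrap_network_test(
        tensor.cbar, response, patients=patients, B=B, seed=seed + 10_000, exhaustive=False
    )
    return float(res.loc[FOCAL_PAIR, "p"])


def power_replicate(seed: int, delta: float, B: int = 999) -> dict:
    """One planted-effect replicate: 10v10 tumors, IL15 ligand shift.

    Returns whether every planted pathway reached BH q < 0.05 on the focal
    pair and whether the focal pair attained the top |z| in the network
    randomization test.
    """
    effects = [
        PlantedEffect("Cancer", "Myeloid", p, delta, "sensitive") for p in PLANTED_PATHWAYS
    ]
    cfg = benchmark_cohort_config(
        n_patients_per_group=10, n_cells_per_sample=300, planted_effects=effects, seed=seed
    )
    ds, _ = simulate_cohort(cfg)
    _, tensor = score_cohort(ds, cfg.lr_database())
    response = ds.obs.groupby("patient")["response"].first()
    patients = ds.obs.groupby("sample")["patient"].first()
    net = bootstrap_network_test(
        tensor.cbar, response, patients=patients, B=B, seed=seed + 20_000, exhaustive=False
    )
    diff = differential_lr_test(
        tensor, response, patients=patients, sender="Cancer", receiver="Myeloid"
    )
    return {
        "detected": bool((diff.loc[PLANTED_PATHWAYS, "q"] < 0.05).all()),
        "top_pair": bool(net["z"].abs().idxmax() == FOCAL_PAIR),
        "z_focal": float(net.loc[FOCAL_PAIR, "z"]),
    }


def six_tumor_network_test(seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3v3 cohort scored and tested with exhaustive label enumeration.

    Returns the test table and the per-tumor C-bar matrix (tumors x
    directed pairs) so an independent oracle can recompute the p-values.
    """
    from .network import _tumor_table

    cfg = benchmark_cohort_config(n_patients_per_group=3, n_cells_per_sample=150, seed=seed)
    ds, _ = simulate_cohort(cfg)
    _, tensor = score_cohort(ds, cfg.lr_database())
    response = ds.obs.groupby("patient")["response"].first()
    patients = ds.obs.groupby("sample")["patient"].first()
    res = bootstrap_network_test(
        tensor.cbar, response, patients=patients, B=20, seed=seed, exhaustive=True
    )
    wide = _tumor_table(tensor.cbar, patients)
    wide["response"] = response.reindex(wide.index)
    return res, wide


def restriction_equivalence_error(seed: int, n_draws: int = 200) -> float:
    """Max relative error between the restricted tumor-wide score and the
    classic ligand x receptor expression product times P-hat."""
    from .communication import lr_comm_score, tumor_wide_received

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        x = float(rng.uniform(0.1, 100.0))
        y = float(rng.uniform(0.1, 100.0))
        p = float(rng.uniform(0.01, 1.0))
        a = tumor_wide_received([x], [p], y)
        b = lr_comm_score(x, y, p)
        worst = max(worst, abs(a - b) / abs(b))
    return worst


def archetype_recovery(seed: int) -> tuple[int, float]:
    """Fit archetypes on 60 samples from 3 planted composition classes."""
    from sklearn.metrics import adjusted_rand_score

    from .composition import fit_archetypes
    from .synthetic import archetype_library, simulate_compositions

    comp, labels = simulate_compositions(
        60,
        archetype_library(),
        ["Cancer", "Myeloid", "Tcell", "Fibroblast", "Endothelial"],
        concentration=40,
        seed=seed,
    )
    model = fit_archetypes(comp, K_range=range(1, 7), seed=seed)
    return model.K, float(adjusted_rand_score(labels, model.labels))


def myeloid_recovery(seed: int, n_cells: int = 1500, noise_sd: float = 0.05) -> dict:
    """Branch-sign accuracy and pseudotime fidelity on a Y-manifold."""
    from scipy.stats import spearmanr

    from .myeloid import (
        classify_differentiation,
        cluster_and_mst,
        fit_division_boundary,
        polarization_score,
        project_pseudotime,
    )
    from .synthetic import simulate_myeloid_manifold

    coords, truth = simulate_myeloid_manifold(n_cells, noise_sd=noise_sd, seed=seed)
    flags = pd.Series(truth.cells["arc_length"] < 0.3, index=coords.index)
    clusters = cluster_and_mst(coords, flags, K_range=range(2, 26), seed=seed)
    pt = project_pseudotime(coords, clusters)
    rho = float(spearmanr(pt["pseudotime"], truth.cells["arc_length"]).statistic)
    state = classify_differentiation(pt["pseudotime"], seed=seed)
    boundary = fit_division_boundary(coords[state == "undifferentiated"])
    pol = polarization_score(coords, pt["pseudotime"], boundary)
    diff = (state == "differentiated").to_numpy()
    branch = truth.cells["branch"].to_numpy()
    eligible = diff & (branch != "root")
    accuracy = float(((pol["side"].to_numpy() > 0) == (branch == "M2"))[eligible].mean())
    return {"branch_accuracy": accuracy, "pseudotime_spearman": rho, "n_eligible": int(eligible.sum())}
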