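"""Synthetic cohorts, myeloid manifolds, and growth curves with known truth.

The generator emulates the data structure of a serially biopsied,
multi-patient single-cell cohort: per-sample cell-type compositions drawn
from planted archetypes, a one-dimensional latent phenotype inside each
broad cell type (so subpopulation binning has real structure to find),
log-normal multiplicative expression noise on the CPM scale, tumor-level
expression random effects, and optional planted differential
ligand-expression effects between response groups.

Expression is simulated directly on the CPM scale for a compact gene panel;
the remaining transcriptome mass is implicit, so panel values are treated
as CPM without forcing each cell to sum to one million.  Raw UMI counts,
doublets, ambient RNA, and batch effects are deliberately not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionDataset, LRDatabase, LRPair

RESPONSE_GROUPS = ("resistant", "sensitive")


@dataclass(frozen=True)
class PlantedEffect:
    """A planted group-specific shift of mean ligand CPM.

    In samples of the flagged response ``group``, the mean CPM of
    ``pathway_id``'s ligand gene in ``sender`` cells is raised by ``delta``
    (before noise) relative to the other group, creating a true
    differential communication on the ``sender -> receiver`` pair.
    """

    sender: str
    receiver: str
    pathway_id: str
    delta: float
    group: str

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("planted effect size delta must be >= 0")
        if self.group not in RESPONSE_GROUPS:
            raise ValueError(f"group must be one of {RESPONSE_GROUPS}, got {self.group!r}")


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    ``archetypes`` maps archetype name -> cell-type proportion vector
    (aligned with ``cell_types``, summing to 1).  Per-sample compositions
    are drawn from a Dirichlet centered on the patient's archetype with
    concentration ``concentration`` (larger = tighter around the
    archetype).  ``expression_means`` gives the mean CPM of each panel gene
    in each cell type; if omitted a generic profile is built in which
    ligand/receptor genes are expressed at 50 CPM in every type and
    background genes at 20 CPM.

    ``gradient_slopes`` maps (gene, cell_type) -> relative slope of the
    gene's mean along the cell's latent phenotype in that type
    (mean * (1 + slope * (u - 1/2)) for latent u ~ Uniform(0, 1)), giving
    subpopulations a real expression gradient.
    """

    n_patients_per_group: int
    cell_types: Sequence[str]
    archetypes: Mapping[str, Sequence[float]]
    n_cells_per_sample: int
    gene_universe: Sequence[str]
    lr_pairs: Sequence[tuple[str, str, str]]
    planted_effects: Sequence[PlantedEffect] = ()
    timepoints: Sequence[int] = (0,)
    expression_means: pd.DataFrame | None = None
    gradient_slopes: Mapping[tuple[str, str], float] = field(default_factory=dict)
    dispersion: float | Mapping[str, float] = 0.6
    tumor_effect_sd: float = 0.05
    concentration: float = 150.0
    treatment: str = "ribociclib"
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_types = list(self.cell_types)
        self.gene_universe = list(self.gene_universe)
        self.lr_pairs = [tuple(p) for p in self.lr_pairs]
        self.planted_effects = list(self.planted_effects)
        self.validate()

    def validate(self) -> None:
        if self.n_patients_per_group < 1:
            raise ValueError("need at least one patient per response group")
        if self.n_cells_per_sample < 30 * len(self.cell_types):
            raise ValueError(
                f"n_cells_per_sample must be >= 30 x number of cell types "
                f"({30 * len(self.cell_types)}), got {self.n_cells_per_sample}"
            )
        for name, props in self.archetypes.items():
            props = np.asarray(props, dtype=float)
            if len(props) != len(self.cell_types):
                raise ValueError(f"archetype {name!r} has wrong length")
            if abs(props.sum() - 1.0) > 1e-8 or np.any(props < 0):
                raise ValueError(f"archetype {name!r} proportions must be >= 0 and sum to 1")
            expected = props * self.n_cells_per_sample
            low = [t for t, e in zip(self.cell_types, expected) if e < 30]
            if low:
                raise ValueError(
                    f"archetype {name!r} gives cell types {low} an expected "
                    f"count below 30 cells per sample"
                )
        known = {pid for _, _, pid in self.lr_pairs}
        for eff in self.planted_effects:
            if eff.pathway_id not in known:
                raise ValueError(
                    f"planted effect references pathway {eff.pathway_id!r} "
                    f"absent from lr_pairs"
                )
            if eff.sender not in self.cell_types or eff.receiver not in self.cell_types:
                raise ValueError(f"planted effect cell types unknown: {eff}")
        panel_genes = {g for pair in self.lr_pairs for g in pair[:2]}
        missing = panel_genes - set(self.gene_universe)
        if missing:
            raise ValueError(f"LR genes missing from gene_universe: {sorted(missing)}")

    def lr_database(self) -> LRDatabase:
        return LRDatabase(LRPair(l, r, pid) for l, r, pid in self.lr_pairs)

    def mean_table(self) -> pd.DataFrame:
        """Gene x cell-type mean CPM table (default profile if unspecified)."""
        if self.expression_means is not None:
            tbl = self.expression_means.reindex(
                index=self.gene_universe, columns=self.cell_types
            )
            if tbl.isna().any().any():
                raise ValueError("expression_means must cover every gene and cell type")
            return tbl.astype(float)
        lr_genes = {g for pair in self.lr_pairs for g in pair[:2]}
        base = pd.DataFrame(
            20.0, index=pd.Index(self.gene_universe), columns=pd.Index(self.cell_types)
        )
        for g in lr_genes:
            base.loc[g] = 50.0
        return base

    def gene_sigma(self) -> pd.Series:
        if isinstance(self.dispersion, Mapping):
            s = pd.Series({g: float(self.dispersion.get(g, 0.6)) for g in self.gene_universe})
        else:
            s = pd.Series(float(self.dispersion), index=pd.Index(self.gene_universe))
        if (s < 0).any():
            raise ValueError("dispersion must be non-negative")
        return s


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated dataset.

    ``samples``: per-sample archetype/response table.  ``cells``: per-cell
    latent phenotype and subpopulation label (for cohorts) or branch and
    arc-length (for myeloid manifolds).  ``planted``: the table of planted
    differential pathways with their true effect sizes.
    """

    samples: pd.DataFrame | None = None
    cells: pd.DataFrame | None = None
    planted: pd.DataFrame | None = None


def simulate_cohort(config: CohortConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a full multi-patient cohort with planted communication effects.

    Patients are split evenly into resistant and sensitive response groups;
    each patient is assigned a composition archetype (uniformly at random)
    shared by all of their timepoint samples.  For each sample, cell-type
    counts are multinomial around a Dirichlet draw of the archetype
    proportions, each cell receives a latent phenotype u ~ Uniform(0, 1),
    and expression is mean CPM x tumor-level random effect x log-normal
    cell noise.  Fixed seed implies byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    mean_tbl = config.mean_table()
    sigma = config.gene_sigma()
    genes = list(config.gene_universe)
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    arch_names = list(config.archetypes)

    # planted deltas: (group, sender_type) -> per-gene additive shift
    delta_by_group_type: dict[tuple[str, str], np.ndarray] = {}
    ligand_of = {pid: lig for lig, _, pid in config.lr_pairs}
    for eff in config.planted_effects:
        key = (eff.group, eff.sender)
        vec = delta_by_group_type.setdefault(key, np.zeros(n_genes))
        vec[gene_pos[ligand_of[eff.pathway_id]]] += eff.delta

    blocks: list[np.ndarray] = []
    obs_rows: list[dict] = []
    sample_rows: list[dict] = []
    cell_rows: list[dict] = []

    patient_idx = 0
    for group in RESPONSE_GROUPS:
        for _ in range(config.n_patients_per_group):
            patient_idx += 1
            patient = f"P{patient_idx:03d}"
            archetype = arch_names[rng.integers(len(arch_names))]
            props = np.asarray(config.archetypes[archetype], dtype=float)
            # tumor-level per-gene expression random effect, shared across
            # that patient's timepoints
            s = config.tumor_effect_sd
            tumor_factor = np.exp(rng.normal(-0.5 * s * s, s, size=n_genes)) if s > 0 else np.ones(n_genes)
            for day in config.timepoints:
                sample = f"{patient}_d{day}"
                p_sample = rng.dirichlet(props * config.concentration) if config.concentration > 0 else props
                counts = rng.multinomial(config.n_cells_per_sample, p_sample)
                sample_rows.append(
                    {
                        "sample": sample,
                        "patient": patient,
                        "day": day,
                        "treatment": config.treatment,
                        "response": group,
                        "archetype": archetype,
                    }
                )
                for ct, n_ct in zip(config.cell_types, counts):
                    if n_ct == 0:
                        continue
                    u = rng.uniform(size=n_ct)
                    means = np.repeat(mean_tbl[ct].to_numpy()[None, :], n_ct, axis=0)
                    for (g, gct), slope in config.gradient_slopes.items():
                        if gct == ct and g in gene_pos:
                            j = gene_pos[g]
                            means[:, j] = means[:, j] * np.clip(1.0 + slope * (u - 0.5), 0.0, None)
                    shift = delta_by_group_type.get((group, ct))
                    if shift is not None:
                        means = means + shift[None, :]
                    sig = sigma.to_numpy()[None, :]
                    noise = np.exp(rng.normal(-0.5 * sig * sig, np.broadcast_to(sig, means.shape)))
                    expr = means * tumor_factor[None, :] * noise
                    blocks.append(expr)
                    for i in range(n_ct):
                        barcode = f"{sample}_{ct}_{i:04d}"
                        obs_rows.append(
                            {
                                "barcode": barcode,
                                "patient": patient,
                                "sample": sample,
                                "day": day,
                                "cell_type": ct,
                                "subtype": "",
                                "treatment": config.treatment,
                                "response": group,
                            }
                        )
                        cell_rows.append(
                            {
                                "barcode": barcode,
                                "latent": u[i],
                                "subpopulation": f"{ct}:q{min(int(u[i] * 3) + 1, 3)}",
                            }
                        )

    matrix = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows).set_index("barcode")
    dataset = ExpressionDataset(matrix, obs, pd.Index(genes))
    truth = GroundTruth(
        samples=pd.DataFrame(sample_rows).set_index("sample"),
        cells=pd.DataFrame(cell_rows).set_index("barcode"),
        planted=pd.DataFrame(
            [
                {
                    "sender": e.sender,
                    "receiver": e.receiver,
                    "pathway_id": e.pathway_id,
                    "delta": e.delta,
                    "group": e.group,
                }
                for e in config.planted_effects
            ],
            columns=["sender", "receiver", "pathway_id", "delta", "group"],
        ),
    )
    return dataset, truth


def simulate_compositions(
    n_samples: int,
    archetypes: Mapping[str, Sequence[float]],
    cell_types: Sequence[str],
    concentration: float = 40.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw sample compositions from planted archetypes (Dirichlet noise).

    Returns a samples x cell-types proportion matrix and the true archetype
    label of each sample.  Samples cycle through the archetypes so the
    design is balanced.
    """
    rng = np.random.default_rng(seed)
    names = list(archetypes)
    rows, labels = [], []
    for i in range(n_samples):
        name = names[i % len(names)]
        props = np.asarray(archetypes[name], dtype=float)
        rows.append(rng.dirichlet(props * concentration))
        labels.append(name)
    comp = pd.DataFrame(
        rows, index=[f"S{i + 1:03d}" for i in range(n_samples)], columns=list(cell_types)
    )
    return comp, pd.Series(labels, index=comp.index, name="archetype")


def simulate_myeloid_manifold(
    n_cells: int,
    branch_lengths: tuple[float, float] = (1.0, 1.0),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Place cells on a Y-shaped monocyte -> M1/M2 differentiation manifold.

    The root segment runs from (0, 0) to (1, 0) along embedding axis 1; the
    two branches leave its end at +/- 45 degrees, the M2-like branch on the
    positive axis-2 side and the M1-like branch on the negative side.
    Cells are assigned to segments with probability proportional to segment
    length and placed uniformly along them, then perturbed by isotropic
    Gaussian noise.  Truth records each cell's branch (root/M1/M2) and its
    arc-length from the origin along the polyline.
    """
    if n_cells < 90:
        raise ValueError("n_cells must be >= 90")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    l1, l2 = branch_lengths
    if l1 <= 0 or l2 <= 0:
        raise ValueError("branch lengths must be positive")
    rng = np.random.default_rng(seed)
    lengths = np.array([1.0, l1, l2])
    seg = rng.choice(3, size=n_cells, p=lengths / lengths.sum())
    pos = rng.uniform(size=n_cells) * lengths[seg]
    c = 1.0 / math.sqrt(2.0)
    x = np.where(seg == 0, pos, 1.0 + pos * c)
    y = np.where(seg == 0, 0.0, np.where(seg == 1, -pos * c, pos * c))
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, n_cells)
        y = y + rng.normal(0, noise_sd, n_cells)
    barcodes = [f"cell_{i:05d}" for i in range(n_cells)]
    coords = pd.DataFrame({"axis1": x, "axis2": y}, index=barcodes)
    branch = np.where(seg == 0, "root", np.where(seg == 1, "M1", "M2"))
    arc = np.where(seg == 0, pos, 1.0 + pos)
    truth = GroundTruth(
        cells=pd.DataFrame({"branch": branch, "arc_length": arc}, index=pd.Index(barcodes, name="barcode"))
    )
    return coords, truth


def simulate_growth_curves(
    n0: float,
    rate_per_condition: pd.DataFrame,
    observation_times: Sequence[float],
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential spheroid abundance series N(t) = n0 * exp(rate * t) * (1 + eps).

    ``rate_per_condition`` carries one row per experimental condition with
    columns ``line``, ``culture``, ``ribo_uM``, ``il15_ng_ml`` and ``rate``
    (per hour).  ``eps`` is multiplicative Gaussian noise with coefficient
    of variation ``noise_cv``.  Returns a long table with one row per
    (condition, replicate, time).
    """
    if n0 <= 0:
        raise ValueError("initial abundance n0 must be positive")
    times = np.asarray(list(observation_times), dtype=float)
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("observation_times must start at 0 and be strictly increasing")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    required = {"line", "culture", "ribo_uM", "il15_ng_ml", "rate"}
    missing = required - set(rate_per_condition.columns)
    if missing:
        raise ValueError(f"rate_per_condition is missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for _, cond in rate_per_condition.iterrows():
        for rep in range(1, n_replicates + 1):
            n_t = n0 * np.exp(float(cond["rate"]) * times)
            if noise_cv > 0:
                n_t = n_t * (1.0 + rng.normal(0, noise_cv, size=times.size))
            for t, n in zip(times, n_t):
                rows.append(
                    {
                        "line": cond["line"],
                        "culture": cond["culture"],
                        "ribo_uM": cond["ribo_uM"],
                        "il15_ng_ml": cond["il15_ng_ml"],
                        "replicate": rep,
                        "time_h": t,
                        "abundance": n,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference study conditions used by the package's own benchmark experiments.
# ---------------------------------------------------------------------------

#: Ligand-receptor panel for benchmark cohorts.  IL15 signals through two
#: receptors (IL15RA and the shared IL2RB chain), so a planted IL15 ligand
#: effect touches two pathways of the panel, as a real cytokine program
#: would.
BENCHMARK_LR_PAIRS: list[tuple[str, str, str]] = [
    ("IL15", "IL15RA", "IL15_IL15RA"),
    ("IL15", "IL2RB", "IL15_IL2RB"),
    ("CSF1", "CSF1R", "CSF1_CSF1R"),
    ("CCL2", "CCR2", "CCL2_CCR2"),
    ("TGFB1", "TGFBR1", "TGFB1_TGFBR1"),
    ("EGF", "EGFR", "EGF_EGFR"),
]

BENCHMARK_CELL_TYPES = ["Cancer", "Myeloid", "Tcell"]


def _benchmark_means() -> pd.DataFrame:
    """Cell-type specific mean CPM profile for the benchmark panel.

    Receptors are expressed only in their designated receiver type.  This
    keeps planted ligand effects specific to the planted directed pair:
    the tumor-wide score factorizes into a sender and a receiver term, so
    any receiver type expressing the receptor would — correctly — inherit
    the ligand shift after standardization, and the planted truth would no
    longer name a unique differential pair.
    """
    genes = sorted({g for p in BENCHMARK_LR_PAIRS for g in p[:2]}) + [
        "CD14",
        *(f"BG{i:02d}" for i in range(1, 21)),
    ]
    tbl = pd.DataFrame(5.0, index=pd.Index(genes), columns=pd.Index(BENCHMARK_CELL_TYPES))
    tbl.loc[[f"BG{i:02d}" for i in range(1, 21)]] = 20.0
    # ligands
    tbl.loc["IL15", "Cancer"] = 50.0
    tbl.loc["CSF1", ["Cancer", "Tcell"]] = 50.0
    tbl.loc["CCL2", ["Cancer", "Myeloid"]] = 50.0
    tbl.loc["TGFB1"] = 40.0
    tbl.loc["EGF", "Cancer"] = 50.0
    # receptors (receiver-type specific)
    for receptor in ("IL15RA", "IL2RB", "CSF1R", "CCR2", "EGFR", "TGFBR1"):
        tbl.loc[receptor] = 0.0
    tbl.loc["IL15RA", "Myeloid"] = 50.0
    tbl.loc["IL2RB", "Myeloid"] = 50.0
    tbl.loc["CSF1R", "Myeloid"] = 50.0
    tbl.loc["CCR2", "Myeloid"] = 50.0
    tbl.loc["TGFBR1", "Tcell"] = 40.0
    tbl.loc["EGFR", "Cancer"] = 50.0
    # monocyte marker, declining along the myeloid latent phenotype
    tbl.loc["CD14", "Myeloid"] = 60.0
    return tbl


def benchmark_cohort_config(
    n_patients_per_group: int = 10,
    n_cells_per_sample: int = 300,
    planted_effects: Sequence[PlantedEffect] = (),
    seed: int = 0,
) -> CohortConfig:
    """Reference cohort: 3 cell types, 6-pathway cytokine/growth-factor panel.

    One mixed archetype; latent-phenotype gradients on the myeloid receptor
    genes and the CD14 monocyte marker give subpopulation binning real
    structure.  Used by the package's calibration and power benchmarks.
    """
    means = _benchmark_means()
    return CohortConfig(
        n_patients_per_group=n_patients_per_group,
        cell_types=BENCHMARK_CELL_TYPES,
        archetypes={"mixed": [0.5, 0.3, 0.2]},
        n_cells_per_sample=n_cells_per_sample,
        gene_universe=list(means.index),
        lr_pairs=BENCHMARK_LR_PAIRS,
        planted_effects=planted_effects,
        timepoints=(0,),
        expression_means=means,
        gradient_slopes={
            ("IL15RA", "Myeloid"): 0.6,
            ("CSF1R", "Myeloid"): 0.4,
            ("CD14", "Myeloid"): -1.2,
            ("EGFR", "Cancer"): 0.5,
        },
        dispersion=0.6,
        tumor_effect_sd=0.05,
        concentration=150.0,
        seed=seed,
    )


def archetype_library() -> dict[str, list[float]]:
    """Three planted tumor-composition archetypes over five cell types.

    Ordered as [Cancer, Myeloid, Tcell, Fibroblast, Endothelial]: an
    immune-hot/diverse archetype, a cancer-dominated archetype, and a
    fibroblast/endothelial-enriched archetype.
    """
    return {
        "immune_hot": [0.25, 0.25, 0.30, 0.12, 0.08],
        "cancer_dominated": [0.70, 0.08, 0.07, 0.10, 0.05],
        "stromal_enriched": [0.30, 0.10, 0.08, 0.32, 0.20],
    }
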