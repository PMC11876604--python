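# tmecomm

Population-level ("tumor-wide") cell–cell communication analysis for
multi-patient, multi-timepoint single-cell cohorts, built for studies of
treatment resistance in the tumor microenvironment (TME): which cell types
talk to which, through which ligand–receptor (LR) pathways, and how those
conversations differ between tumors that keep growing under therapy
(resistant) and tumors that shrink (sensitive).

## What it computes

**Tumor-wide communication.** Classic cell–cell interaction scores multiply
one sender cell's ligand expression by one receiver cell's receptor
expression. `tmecomm` extends this to the whole tumor ecosystem through a
ligand balance model: the TME concentration *S* of a signaling ligand obeys

    dS/dt = Σᵢ σ xᵢ Pᵢ − Σⱼ qⱼ yⱼ γ Pⱼ S − μS,

where subpopulation *i* produces ligand in proportion to its mean expression
*xᵢ* and abundance *Pᵢ*, and removal happens by decay/diffusion (μ) and
receptor-bound uptake (γ, qⱼ). At steady state, with small internalization
qⱼ, the signal received through pathway *k* by a cell of subpopulation *j* is

    C_jk ∝ y_jk Σᵢ x_ik P̂ᵢ,

the receptor expression times the abundance-weighted ligand production of
*every* subpopulation in the sample. Subpopulations are equal-width phenotype
bins (≥ 30 cells) inside each broad cell type; cell-type-level scores sum
over the sender type's bins and average over the receiver type's bins
weighted by abundance. Scores are standardized per pathway across samples
and summarized per directed cell-type pair by the median standardized score
(C̄).

**Network contrasts.** Resistant-vs-sensitive differences in C̄ are tested by
shuffling tumor response labels (tumors, not biopsies, are the exchangeable
unit), giving a z statistic and a rank p-value per directed pair with Holm
control; small cohorts are tested exactly by enumerating all label
assignments. Per-pathway differences are tested on log(1 + C) with BH-FDR
control.

**Compositional archetypes.** Sample compositions are compared by
logit-Euclidean distance, embedded with UMAP, and clustered by a Gaussian
mixture with BIC-selected component count; validation cohorts are projected
through the frozen model. Shannon diversity summarizes immune composition.

**Myeloid polarization.** Myeloid cells are clustered (GMM/BIC), a minimum
spanning tree over cluster centroids rooted at the monocyte-dominated
cluster provides pseudotime by orthogonal projection, a two-state mixture
splits undifferentiated from differentiated cells, a smoothing-spline
boundary through the undifferentiated cells separates the M1-like from the
M2-like side, and polarization is the signed pseudotime divergence from that
boundary (positive = M2-like). Gene trends along polarization are ranked by
spline-regression F statistics.

**Growth assay.** The relative growth rate of spheroid co-cultures is
rgr = (ln N(t₇₅) − ln N(t₀)) / 75 h, with per-condition summaries and IL-15
dose trends.

A synthetic cohort generator plants known composition archetypes, phenotype
gradients, differential LR effects, branching myeloid manifolds, and
exponential growth curves, so every stage is benchmarked against ground
truth without any external download.

## Worked example

Simulate a 10 vs 10 tumor cohort (3 cell types, 6-pathway cytokine panel)
in which sensitive tumors' cancer cells over-express IL-15 — which signals
to myeloid cells through both IL15RA and IL2RB — then score and contrast:

```python
import tmecomm as tc
from tmecomm.synthetic import benchmark_cohort_config, PlantedEffect
from tmecomm.benchmarks import score_cohort

effects = [
    PlantedEffect("Cancer", "Myeloid", "IL15_IL15RA", 31.0, "sensitive"),
    PlantedEffect("Cancer", "Myeloid", "IL15_IL2RB", 31.0, "sensitive"),
]
cfg = benchmark_cohort_config(n_patients_per_group=10, n_cells_per_sample=300,
                              planted_effects=effects, seed=1)
dataset, truth = tc.simulate_cohort(cfg)
partition, tensor = score_cohort(dataset, cfg.lr_database())
response = dataset.obs.groupby("patient")["response"].first()
patients = dataset.obs.groupby("sample")["patient"].first()

net = tc.bootstrap_network_test(tensor.cbar, response, patients=patients,
                                B=999, seed=8)
print(net[["obs_diff", "z", "p", "p_holm"]].round(3))
```

```
                  obs_diff      z      p  p_holm
sender  receiver
Cancer  Cancer       0.000  0.000  1.000   1.000
        Myeloid     -0.622 -3.174  0.002   0.018
        Tcell        0.000  0.000  1.000   1.000
Myeloid Cancer       0.000  0.000  1.000   1.000
        Myeloid     -0.098 -0.302  0.756   1.000
...
```

The planted Cancer→Myeloid pair is the only one that survives Holm
correction: its median standardized communication is 0.62 lower in
resistant tumors (z = −3.17). The per-pathway test localizes the signal to
the two IL-15 pathways:

```python
diff = tc.differential_lr_test(tensor, response, patients=patients,
                               sender="Cancer", receiver="Myeloid")
print(diff[["est", "t", "q"]].round(4))
```

```
                 est        t    q
pathway
CCL2_CCR2     0.0064   0.1020  1.0
CSF1_CSF1R    0.0510   0.6007  1.0
EGF_EGFR      0.0000   0.0000  1.0
IL15_IL15RA  -0.8107 -14.1846  0.0
IL15_IL2RB   -0.7785 -11.4928  0.0
TGFB1_TGFBR1  0.0000   0.0000  1.0
```

`est` is the resistant-minus-sensitive difference in mean log(1 + C): both
IL-15 pathways are strongly reduced in resistant tumors (q ≈ 0), the four
null pathways are flat.

The same chain runs from the shell:

```sh
tmecomm run-all --config pipeline.yaml --outdir results/ --seed 1
```

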