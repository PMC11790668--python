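# forestdyn

Drivers of aboveground-biomass dynamics (ΔAGB) in stem-mapped forest
census plots.

`forestdyn` is for forest community ecologists working with
CTFS-ForestGEO-style plot data: repeated stem censuses (DBH ≥ 1 cm) on a
grid of 20 m × 20 m quadrats, a species table with traits and allometry
coefficients, a phylogeny, and plot topography. It answers, for each
census interval and habitat stratum, *which dimensions of biodiversity —
taxonomic, structural, phylogenetic, functional — and which topographic
factors best explain where biomass was gained or lost*.

## What it computes

**Biomass.** Stem AGB from the two-step allometry
`H = a·D^b·CF`, `AGB_kg = 0.0673·(WD·D²·H)^0.976` (D in cm, WD in
g cm⁻³), with pooled height coefficients and hierarchical wood-density
imputation (genus → family → pool) where species data are missing.
Quadrat AGB in Mg ha⁻¹ and interval ΔAGB follow.

**Diversity.** Per quadrat and census, eleven indices: Shannon `H`,
Gini–Simpson `D`, Pielou `J`; stand density `SD` and `CV_DBH = σ/μ`;
phylogenetic `MPD`/`MNTD` as null-model standardized effect sizes,

```
SES = (observed − mean(null)) / sd(null)
```

under a seeded taxa-shuffle null (999 iterations by default); their
functional-trait analogues `traitMPD`/`traitMNTD` (sign-flipped, on a
UPGMA dendrogram of Gower trait dissimilarity); and `FDis`/`RaoQ` on the
raw Gower matrix. Change values (`cH` … `cRaoQ`) per interval.

**Topography.** Elevation, slope, aspect and convexity per quadrat from
the corner-elevation lattice, plus H1/H2/H3 (valley/hillside/ridge)
habitat labels.

**Drivers.** Per interval × stratum: z-scoring of ΔAGB and all 26
covariates, iterative VIF filtering (threshold 5), exhaustive lowest-AIC
Gaussian GLM subset selection, Chevan–Sutherland hierarchical
partitioning of R² into per-predictor independent contributions, and
per-dimension relative importance (%). Wilcoxon rank-sum comparisons of
AGB across censuses per stratum.

**Synthetic study system.** A seeded generator produces a full 5-ha-style
study — birth–death phylogeny, genus-structured traits, V-shaped valley
with 50/45/25 habitat strata over 120 quadrats, three censuses with
growth, size-biased disturbance mortality and recruitment — including
optional *embedded* linear covariate effects on ΔAGB with recorded
ground truth, so the whole chain is testable without field data. See
`docs/methods.md` for every modelling choice.

## Worked example

Simulate a plot and run the full pipeline from the shell (the library
API — `simulate_study`, `run_pipeline`, and the per-stage functions —
does the same in Python):

```
$ cat study.yaml
n_species: 60
initial_stems_mean: 80
seed: 1
$ cat pipeline.yaml
null_iterations: 199
seed: 1
$ forestdyn simulate --out demo/in --config study.yaml
wrote synthetic study (38564 stem records) to demo/in
$ forestdyn run demo/in --out demo/out --config pipeline.yaml
pipeline finished: 8 driver cells -> demo/out
$ forestdyn report demo/out
[1-2 | whole] n=120 R2=0.780 AIC=-166.5 selected=SD,CV_DBH,cJ,cCV_DBH,cMNTD,ctraitMPD | structural 94.4%, phylogenetic 3.9%, functional 1.1%, taxonomic 0.7%
[1-2 | H1   ] n= 50 R2=0.815 AIC=-73.4 selected=CV_DBH,MPD,cCV_DBH,cMNTD | structural 96.1%, phylogenetic 3.9%
[1-2 | H2   ] n= 45 R2=0.946 AIC=-110.2 selected=elevation,aspect,convexity,H,CV_DBH,cJ,cCV_DBH,cMPD,cMNTD | structural 85.6%, topographic 9.2%, phylogenetic 3.4%, taxonomic 1.7%
[1-2 | H3   ] n= 25 R2=0.688 AIC=-14.1 selected=CV_DBH,MNTD,cH,cJ,cCV_DBH,ctraitMPD | structural 57.0%, phylogenetic 16.9%, taxonomic 13.6%, functional 12.5%
[2-3 | whole] n=120 R2=0.491 AIC=-64.0 selected=slope,SD,CV_DBH,cJ,cCV_DBH,cMPD,ctraitMNTD | structural 88.5%, taxonomic 5.1%, topographic 3.6%, functional 1.6%, phylogenetic 1.4%
[2-3 | H1   ] n= 50 R2=0.554 AIC=-31.4 selected=J,CV_DBH,cCV_DBH | structural 96.8%, taxonomic 3.2%
[2-3 | H2   ] n= 45 R2=0.553 AIC=-21.2 selected=slope,SD,CV_DBH,cJ,cCV_DBH,cMPD | structural 68.7%, topographic 14.2%, taxonomic 11.5%, phylogenetic 5.6%
[2-3 | H3   ] n= 25 R2=0.562 AIC=-5.6 selected=aspect,H,CV_DBH,MPD,cJ,ctraitMNTD | phylogenetic 26.5%, taxonomic 26.5%, topographic 21.9%, structural 13.8%, functional 11.3%
```

Each line is one interval × stratum model: how many quadrats entered
(`n`), the variance explained by the lowest-AIC model (`R2`), the
selected covariates, and the share of relative importance each diversity
dimension carries. Here the first interval contains a size-biased
disturbance, so structural diversity (stand density and DBH variation)
dominates the biomass change everywhere except the lightly-disturbed
ridge — exactly the behaviour the generator embeds. Full coefficient
tables, AGB/ΔAGB, diversity and topography CSVs, a JSON summary and a
provenance record (config hash + seed; re-running the same
configuration reproduces every file byte for byte) land in `demo/out`.

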