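# Methods

This note documents the models, conventions and numerical choices behind
`forestdyn`, and what the synthetic study system does and does not
emulate.

## Biomass model

Stem aboveground biomass (AGB) is estimated in two steps from diameter
at breast height (DBH, cm). Height comes from a species-specific power
law

```
H = a · D^b · CF
```

with `CF` a back-transform correction factor for the log-scale
regression the coefficients come from. Species without fitted
coefficients use a pooled all-species set (a flag the species table
carries); `CF` defaults to 1 when untabulated. Stem biomass then follows
the improved pan-tropical allometry

```
AGB_kg = 0.0673 · (WD · D² · H)^0.976
```

with wood density `WD` in g cm⁻³. The output is taken to be kilograms
per stem — the standard for this allometry family — and the conversion
to quadrat-level Mg ha⁻¹ (`× 10/area_m²`) is explicit and configurable.
Every tagged stem of a multi-stemmed tree is biomassed and summed, the
CTFS-ForestGEO convention. Stems with status other than `alive`
contribute zero. ΔAGB between censuses is strictly later-minus-earlier,
so intervals telescope.

Missing wood densities are imputed hierarchically: mean over congeners
with observed WD in the same climate region, else confamilials, else the
pool-wide mean (logged as a fallback); provenance flags are kept per
species.

## Topography

Quadrat topography follows the convention long used for stem-mapped
forest-dynamics plots, computed from the corner-elevation lattice:
elevation is the mean of the four corners; slope is the mean angular
slope of the four planes obtained by omitting each corner in turn;
aspect is the compass bearing of steepest descent of the least-squares
plane (degrees clockwise from north, undefined on perfectly flat
quadrats); convexity is the quadrat elevation minus the mean of its up
to eight neighbours. Edge quadrats use the centre-minus-own-corner-mean
convention, which is identically zero on the bilinear surface implied by
corner-only data — a known, documented degeneracy rather than a bug.
Aspect enters driver models untransformed by default (a `northness =
cos(aspect)` option exists); the circularity caveat applies to the raw
form.

## Diversity covariates

Eleven indices per quadrat and census, in four dimensions:

* **Taxonomic** — Shannon–Wiener `H` (natural log), Simpson `D` in the
  Gini–Simpson form `1 − Σp²` by default (so that larger = more diverse,
  consistent with its use alongside `H` and `J`; the dominance form is a
  config switch), Pielou `J = H/ln S`, undefined for monocultures.
* **Structural** — stand density `SD` (stems ≥ 1 cm DBH) and
  `CV_DBH = σ/μ` with the sample (n−1) standard deviation; undefined
  below two stems.
* **Phylogenetic** — standardized effect sizes of mean pairwise distance
  (MPD) and mean nearest-taxon distance (MNTD) on the phylogeny's
  patristic distances.
* **Functional** — sign-flipped SES of MPD/MNTD on the cophenetic
  distances of a UPGMA dendrogram built from Gower trait dissimilarity
  (wood density, maximum height, life form; numeric traits range-scaled
  over the pool, equal weights), plus functional dispersion (FDis) and
  Rao's quadratic entropy (RaoQ) on the raw Gower matrix. The −1 flip
  follows the convention that larger trait-SES values should read as
  greater divergence.

Change values (`cH` … `cRaoQ`) are later-minus-earlier differences;
missing values propagate and are excluded listwise from driver models,
with counts logged.

### Null model and SES conventions

The default null is the taxa shuffle: community richness is held fixed
and species identities are drawn uniformly without replacement from the
pool (equivalently, labels are permuted on the distance matrix), 999
iterations, seeded. An occupancy-and-richness-preserving independent
swap of the community matrix is available by config. MPD/MNTD are
presence-based by default — the defining formulas are written over
species, not individuals — with abundance weighting available.

Two sd conventions coexist deliberately. Monte-Carlo SES divides by the
sample (n−1) standard deviation of the simulated null values, the usual
estimator of the null distribution's spread. Exhaustive enumeration
(available for small pools, and the test oracle) divides by the
population (n) standard deviation over all C(pool, richness) equally
likely communities, because the enumerated set *is* the entire null
distribution; the Monte-Carlo estimator converges to exactly this value,
so the two modes agree in the large-iteration limit. Degenerate nulls
(sd = 0, e.g. a community saturating the pool) yield missing values.

FDis follows the Laliberté–Legendre construction: principal-coordinate
embedding of the Gower matrix with negative eigenvalues truncated,
abundance-weighted centroid, abundance-weighted mean distance to it.

## Driver analysis

For each census interval × stratum (whole plot, H1, H2, H3) the
per-quadrat ΔAGB is modelled on 26 covariates: four topographic
variables, the eleven indices at the interval's first census, and their
eleven change values.

* All variables, response included, are z-scored (sample sd), so
  coefficients are standardized effects; zero-variance columns are
  dropped with a warning.
* Collinearity: variance inflation factors are recomputed iteratively
  and the single worst predictor is removed while any VIF exceeds 5;
  perfectly collinear predictors (infinite VIF) go first.
* Model selection: Gaussian identity-link GLM (ordinary least squares),
  exhaustive over all non-empty predictor subsets up to 15 predictors
  with `AIC = n·ln(RSS/n) + 2(k+2)` (intercept and variance counted);
  ties break toward fewer predictors, then lexicographically. Above 15
  predictors a bidirectional stepwise search from the empty model is
  used and logged. Subset size is capped at n − 3 so the residual
  variance stays estimable.
* Relative importance: Chevan–Sutherland hierarchical partitioning of R²
  over the selected predictors (capped at 12 — the method is exponential
  in k; when a selected model is larger, the 12 strongest predictors by
  p-value are partitioned and the restriction is reported). Independent
  contributions provably sum to the full-model R² and equal the average
  over all predictor orderings of sequential R² increments. Per-dimension
  importances sum member predictors within taxonomic / structural /
  phylogenetic / functional / topographic groups; initial and change
  values share their base variable's dimension.
* AGB levels across censuses are compared per stratum with the two-sided
  Wilcoxon rank-sum (Mann–Whitney) test — exact where SciPy supports it,
  otherwise the tie- and continuity-corrected normal approximation. The
  test is unpaired, as named, although quadrats are paired across
  censuses; a paired signed-rank option is exposed. Stars at
  0.05/0.01/0.001. No multiple-testing correction is applied across
  cells.
* Strata with fewer than 10 complete quadrats are skipped with a
  warning. The habitat-stratified models are fitted per interval, not
  pooled.

Whether relative-importance percentages should be computed over the
selected model only or over all candidates is genuinely open; they are
computed here over the AIC-best model's predictors.

## Synthetic study system

The generator emulates a 5-ha subtropical forest dynamics plot: a
10 × 12 grid of 20 m × 20 m quadrats (120 analysed cells), three
censuses at 5-year intervals, a V-shaped valley (low-valley H1,
mid-hillside H2, high-ridge H3 strata of 50/45/25 quadrats via exact
elevation terciles), about 147 stems per quadrat, ~160 species, and a
size-biased disturbance pulse in the first interval concentrated in the
valley. Specifics:

* **Species pool** — constant-rate birth–death phylogeny (λ=1, μ=0.2)
  rescaled to unit depth; genera and families are nested clades cut from
  it, so taxonomy and phylogeny agree. Wood density is lognormal with
  median 0.55 g cm⁻³ and genus-level structure (making congener
  imputation meaningful); 14.9% of species have WD deliberately missing.
  Life form is sampled per genus (70% evergreen broad-leaved, 25%
  deciduous, 5% coniferous). 47/161 of species get fitted height
  coefficients; the rest fall back to the pooled set.
* **Community assembly** — per-species Dirichlet habitat affinities
  crossed with lognormal regional dominance give log-series-like rank
  abundances and compositional turnover across habitats.
* **Size structure** — initial DBH is 1 + lognormal(0.85, 1.25) cm,
  capped at 120 cm; these values were chosen so that quadrat AGB
  densities fall near 190 Mg ha⁻¹, the magnitude typical of subtropical
  evergreen broad-leaved forest, and decline by roughly 15% through the
  disturbance interval before partially recovering.
* **Dynamics** — non-negative Gaussian diameter increments (1.0 ± 0.6 cm
  per interval); tree-level background mortality 6% per interval;
  disturbance-interval mortality additionally
  `0.06 · w(habitat) · (D/10)^0.8` with weights 1.0/0.5/0.3 for
  H1/H2/H3, so large valley trees die preferentially; Poisson
  recruitment of 25 new 1–2 cm stems per quadrat per interval. Mortality
  and recruitment rates are plausibility choices, not calibrated field
  rates. A stem that dies appears once, flagged dead, in the census
  closing that interval.
* **Embedded effects** — optionally, quadrat ΔAGB in each interval is
  made to equal `Σ βᵢ·xᵢ + N(0, noise_sd)` for chosen covariates xᵢ
  (their realized per-quadrat values, raw scale), by uniformly rescaling
  stem biomass within each quadrat through an `agb_scale` column the
  biomass module honors. DBH is untouched, so every diversity covariate
  keeps its natural value — cause and effect stay separable, and with
  `noise_sd = 0` the regression of ΔAGB on the realized covariate
  returns β to machine precision. The truth record stores coefficients,
  realized covariates and targets. Quadrats whose biomass cannot reach a
  (rare, extreme) target are left unadjusted and counted in the log.

What the generator does **not** emulate: spatially explicit stem
mapping, dispersal and neighbourhood competition, climate forcing,
measurement error in DBH, and multi-census species turnover beyond
habitat filtering. Passing tests therefore demonstrate that the
estimators and the selection/partitioning machinery behave correctly
under a controlled, realistic-magnitude data-generating process — not
that any particular field system obeys the embedded models.

## Validation experiments and problem sizes

The test suite checks every estimator against an independent oracle:
closed-form allometry values; exhaustively enumerated SES; brute-force
subset enumeration for AIC; all-orderings averaging for hierarchical
partitioning; direct VIF recomputation (statsmodels) after filtering;
and exact rank-test enumeration. Calibration: SES of communities drawn
from the null itself has |mean| ≤ 0.1 and sd within [0.85, 1.15] over
500 replicates (999 iterations each).

The embedded-effect recovery experiment uses a 120-quadrat plot,
40-species pool, two censuses, ~60 stems per quadrat and 99 null
iterations per SES — sizes at which one replicate takes about a second —
with effect +0.5, noise sd 1; across 200 seeded replicates the effect
is selected with the correct sign well above the 90% requirement.

## Known limitations

* Convexity is exactly zero for edge quadrats (see above), which can
  make it near-constant in small grids or edge-dominated strata; it is
  then dropped by the zero-variance guard.
* Stepwise fallback above 15 post-VIF predictors is a heuristic; the
  exhaustive guarantee applies only at or below `max_exhaustive`.
* AIC-based selection is known to be liberal: with pure noise it admits
  spurious predictors at a non-trivial rate. The recovery experiment
  measures sign recovery of a true effect, not the false-selection rate.
* SES values computed with finitely many null iterations carry
  Monte-Carlo noise (≈ 1/√M relative); change values of SES compound
  two such estimates.
* The Wilcoxon comparisons across three censuses on the same quadrats
  ignore the pairing by default, matching the named test; the paired
  option is usually more powerful.
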