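"""Synthetic stem-mapped forest study system.

Generates everything the analysis pipeline consumes: a species pool with
taxonomy, traits, height-allometry coefficients and a birth–death
phylogeny; a V-shaped valley landscape of 20 m quadrats classified into
low-valley (H1), mid-hillside (H2) and high-ridge (H3) habitats; and a
series of censuses linked by diameter growth, size-biased disturbance
mortality and recruitment. Defaults emulate a 5-ha subtropical plot:
a 10 x 12 grid of 20 m x 20 m quadrats (120 analysed cells, habitat
counts 50/45/25), ~147 stems per quadrat, three censuses at 5-year
intervals, and a disturbance pulse in the first interval that kills
preferentially large stems, most strongly in the valley.

Optionally, known linear effects of chosen covariates on quadrat ΔAGB
are embedded by rescaling stem biomass (an ``agb_scale`` column the
biomass module honors), leaving all DBH-derived covariates untouched, so
that driver-recovery experiments have a ground truth.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from dendropy.model import birthdeath
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import squareform

from . import diversity as dv
from .biomass import SpeciesPool, quadrat_agb
from .errors import InvalidConfigurationError
from .topography import habitats_from_elevation, quadrat_id, quadrat_topography

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DisturbanceConfig:
    """Size-biased mortality pulse applied in one census interval."""

    interval_index: int = 0          # 0-based interval (census 1 -> 2)
    mortality_base: float = 0.06     # disturbance mortality at DBH 10 cm, weight 1
    size_bias_exponent: float = 0.8  # mortality ∝ (DBH/10)**exponent
    habitat_weights: dict = field(default_factory=lambda: {"H1": 1.0, "H2": 0.5, "H3": 0.3})


@dataclass(frozen=True)
class GrowthConfig:
    dbh_increment_mean: float = 1.0  # cm per interval
    sd: float = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 160
    plot_cols: int = 10
    plot_rows: int = 12
    quadrat_side: float = 20.0
    n_censuses: int = 3
    census_interval: int = 5
    habitat_fractions: tuple = (50 / 120, 45 / 120, 25 / 120)
    disturbance: DisturbanceConfig = field(default_factory=DisturbanceConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    recruitment_rate: float = 25.0       # new stems per quadrat per interval
    background_mortality: float = 0.06   # per-interval baseline
    initial_stems_mean: float = 147.0    # Poisson mean per quadrat at census 1
    multi_stem_fraction: float = 0.05    # trees with a tagged second stem
    dbh_lognorm_mu: float = 0.85         # initial DBH = 1 + lognormal(mu, sigma), cm
    dbh_lognorm_sigma: float = 1.25
    dbh_max: float = 120.0
    wd_missing_fraction: float = 0.149
    fitted_height_fraction: float = 47 / 161
    relief: float = 30.0                 # valley-to-ridge elevation range, m
    elevation_base: float = 300.0
    terrain_noise_sd: float = 1.5        # smoothed corner-elevation noise, m
    embedded_effects: tuple = ()         # ((covariate_name, coefficient), ...)
    noise_sd: float = 0.0                # residual sd of the embedded-effect model, Mg/ha
    null_iterations: int = 999           # null draws when realizing SES covariates
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise InvalidConfigurationError("n_species must be >= 2")
        if self.n_censuses < 2:
            raise InvalidConfigurationError("n_censuses must be >= 2")
        if self.plot_cols < 1 or self.plot_rows < 1:
            raise InvalidConfigurationError("corner grid must be at least 2x2")
        fr = np.asarray(self.habitat_fractions, float)
        if fr.min() < 0 or abs(fr.sum() - 1) > 1e-9:
            raise InvalidConfigurationError("habitat_fractions must sum to 1")
        for name, v in [("recruitment_rate", self.recruitment_rate),
                        ("background_mortality", self.background_mortality),
                        ("noise_sd", self.noise_sd),
                        ("mortality_base", self.disturbance.mortality_base)]:
            if v < 0:
                raise InvalidConfigurationError(f"{name} must be >= 0")


@dataclass
class Landscape:
    corner_elevations: np.ndarray
    frame: pd.DataFrame  # topography + habitat per quadrat


@dataclass
class SyntheticStudy:
    species_pool: SpeciesPool
    censuses: pd.DataFrame       # long table over all censuses
    landscape: Landscape
    truth: dict
    config: SimulationConfig


# ---------------------------------------------------------------------------
# species pool


def simulate_species_pool(
    n_species: int,
    seed: int,
    wd_missing_fraction: float = 0.149,
    fitted_height_fraction: float = 47 / 161,
) -> SpeciesPool:
    """Species pool with taxonomy, traits, allometry and a phylogeny.

    The phylogeny is a constant-rate birth–death tree rescaled to unit
    depth; genera and families are nested clades cut from it, so
    congeners share trait structure (wood density and life form vary
    mostly between genera). A configurable fraction of species has wood
    density deliberately missing, to exercise imputation downstream.
    """
    if n_species < 2:
        raise InvalidConfigurationError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1:03d}" for i in range(n_species)]

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.2, num_extant_tips=n_species,
        rng=_random.Random(int(rng.integers(2**31))),
    )
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for leaf, name in zip(tree.leaf_node_iter(), species):
        leaf.taxon.label = name

    coph = phylo_distance_matrix(tree)
    coph = coph.loc[species, species]

    # nested genus/family clades from the phylogeny
    linkage = sch.average(squareform(coph.to_numpy(), checks=False))
    n_gen = max(1, round(n_species / 1.6))
    n_fam = max(1, round(n_species / 3.5))
    gen_id = sch.fcluster(linkage, t=n_gen, criterion="maxclust")
    fam_id = sch.fcluster(linkage, t=n_fam, criterion="maxclust")
    genus = [f"gen{g:03d}" for g in gen_id]
    family = [f"fam{f:02d}" for f in fam_id]

    # genus-structured wood density (lognormal, median 0.55 g/cm3) and Hmax
    uniq_gen = sorted(set(genus))
    gmap = {g: i for i, g in enumerate(uniq_gen)}
    g_wd = rng.normal(0.0, 0.18, size=len(uniq_gen))
    g_h = rng.normal(0.0, 0.25, size=len(uniq_gen))
    lf_choices = np.array(["evergreen broad-leaved", "deciduous broad-leaved", "coniferous"])
    g_lf = rng.choice(lf_choices, size=len(uniq_gen), p=[0.70, 0.25, 0.05])
    wd = np.exp(np.log(0.55) + np.array([g_wd[gmap[g]] for g in genus]) + rng.normal(0, 0.10, n_species))
    hmax = np.exp(np.log(14.0) + np.array([g_h[gmap[g]] for g in genus]) + rng.normal(0, 0.15, n_species))
    life_form = np.array([g_lf[gmap[g]] for g in genus])

    a = np.full(n_species, np.nan)
    b = np.full(n_species, np.nan)
    cf = np.full(n_species, np.nan)
    n_fit = int(round(fitted_height_fraction * n_species))
    fit_idx = rng.choice(n_species, size=n_fit, replace=False)
    a[fit_idx] = rng.uniform(1.5, 3.0, n_fit)
    b[fit_idx] = rng.uniform(0.45, 0.65, n_fit)
    cf[fit_idx] = rng.uniform(1.0, 1.08, n_fit)

    n_missing = int(round(wd_missing_fraction * n_species))
    if n_missing >= n_species:
        raise InvalidConfigurationError("wd_missing_fraction leaves no observed wood density")
    miss_idx = rng.choice(n_species, size=n_missing, replace=False)
    wd[miss_idx] = np.nan

    traits = pd.DataFrame(
        dict(genus=genus, family=family, wd=wd, hmax=hmax, life_form=life_form,
             a=a, b=b, cf=cf, region="subtropical"),
        index=pd.Index(species, name="species"),
    )
    return SpeciesPool(traits, pooled_height=(2.0, 0.55, 1.02), tree=tree)


def phylo_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic (cophenetic) species x species distances from a phylogeny."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(out, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# landscape


def simulate_landscape(config: SimulationConfig) -> Landscape:
    """Corner-elevation grid with a V-shaped valley plus smooth noise.

    The valley floor runs east–west through the middle of the plot;
    elevation rises linearly toward the north and south edges (an
    irregular "V" cross-section). Habitats are elevation terciles sized
    by ``habitat_fractions``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    rows, cols = config.plot_rows, config.plot_cols
    r = np.arange(rows + 1)[:, None]
    c = np.arange(cols + 1)[None, :]
    half = rows / 2.0
    z = config.elevation_base + config.relief * np.abs(r - half) / half + 0.0 * c
    z = z + 0.08 * config.relief * c / max(cols, 1)  # gentle eastward tilt
    z = np.ascontiguousarray(np.broadcast_to(z, (rows + 1, cols + 1)).copy())
    if config.terrain_noise_sd > 0:
        noise = gaussian_filter(rng.normal(0.0, 1.0, size=z.shape), sigma=1.2)
        noise *= config.terrain_noise_sd / max(noise.std(), 1e-12)
        z = z + noise

    frame = quadrat_topography(z, config.quadrat_side)
    frame["habitat"] = habitats_from_elevation(frame, tuple(config.habitat_fractions))
    return Landscape(z, frame)


# ---------------------------------------------------------------------------
# census dynamics


def _initial_census(pool, landscape, config, rng) -> pd.DataFrame:
    n_sp = len(pool.species)
    aff = rng.dirichlet(np.full(3, 0.8), size=n_sp)  # habitat affinity per species
    regional = rng.lognormal(0.0, 1.2, size=n_sp)    # log-series-like dominance
    hab_idx = {"H1": 0, "H2": 1, "H3": 2}

    recs = []
    tree_counter = 0
    for q in landscape.frame.index:
        h = landscape.frame.at[q, "habitat"]
        w = regional * aff[:, hab_idx[h]]
        p = w / w.sum()
        n_q = rng.poisson(config.initial_stems_mean)
        if n_q == 0:
            continue
        counts = rng.multinomial(n_q, p)
        for s_i in np.flatnonzero(counts):
            for _ in range(counts[s_i]):
                tree_counter += 1
                dbh = min(1.0 + rng.lognormal(config.dbh_lognorm_mu, config.dbh_lognorm_sigma),
                          config.dbh_max)
                recs.append((f"T{tree_counter:06d}", "1", pool.species[s_i], q, dbh))
                if rng.random() < config.multi_stem_fraction:
                    d2 = max(1.0, dbh * rng.uniform(0.25, 0.6))
                    recs.append((f"T{tree_counter:06d}", "2", pool.species[s_i], q, d2))
    df = pd.DataFrame(recs, columns=["tree_id", "stem_id", "species", "quadrat", "dbh_cm"])
    df["census"] = 1
    df["status"] = "alive"
    df["agb_scale"] = 1.0
    return df, aff, tree_counter


def _advance_census(prev: pd.DataFrame, interval: int, pool, landscape, config, rng,
                    aff, tree_counter):
    """One census step: growth, mortality, recruitment. Returns (census, counter)."""
    alive = prev[prev["status"] == "alive"].copy()
    growth = np.clip(rng.normal(config.growth.dbh_increment_mean, config.growth.sd, len(alive)),
                     0.0, None)
    alive["dbh_cm"] = alive["dbh_cm"] + growth

    # tree-level mortality, size-biased during the disturbance interval
    hab = landscape.frame["habitat"]
    tree_dbh = alive.groupby("tree_id").agg(dbh=("dbh_cm", "max"), quadrat=("quadrat", "first"))
    p = np.full(len(tree_dbh), config.background_mortality)
    if interval == config.disturbance.interval_index:
        wts = hab.reindex(tree_dbh["quadrat"]).map(config.disturbance.habitat_weights).to_numpy(float)
        p = p + config.disturbance.mortality_base * wts * (tree_dbh["dbh"].to_numpy() / 10.0) ** config.disturbance.size_bias_exponent
    p = np.clip(p, 0.0, 0.95)
    dies = rng.random(len(tree_dbh)) < p
    dead_trees = set(tree_dbh.index[dies])

    nxt = alive.copy()
    nxt["census"] = interval + 2
    nxt.loc[nxt["tree_id"].isin(dead_trees), "status"] = "dead"

    # recruitment of 1-2 cm stems
    hab_idx = {"H1": 0, "H2": 1, "H3": 2}
    regs = []
    for q in landscape.frame.index:
        n_new = rng.poisson(config.recruitment_rate)
        if n_new == 0:
            continue
        w = aff[:, hab_idx[hab.at[q]]]
        p_sp = w / w.sum()
        for s_i in rng.choice(len(p_sp), size=n_new, p=p_sp):
            tree_counter += 1
            regs.append((f"T{tree_counter:06d}", "1", pool.species[s_i], q,
                         rng.uniform(1.0, 2.0), interval + 2, "alive", 1.0))
    if regs:
        rec_df = pd.DataFrame(regs, columns=["tree_id", "stem_id", "species", "quadrat",
                                             "dbh_cm", "census", "status", "agb_scale"])
        nxt = pd.concat([nxt, rec_df], ignore_index=True)
    return nxt.reset_index(drop=True), tree_counter


#: covariates that may carry embedded effects
def _supported_covariates():
    names = set(dv.INDEX_NAMES) | {f"c{n}" for n in dv.INDEX_NAMES}
    names |= {"elevation", "slope", "aspect", "convexity"}
    return names


def _realized_index(name, censuses_needed, census_df, pool, landscape, config, phylo, dendro, gower):
    """Per-quadrat values of one diversity index for the requested censuses."""
    null = dv.NullModelSpec(n_iterations=config.null_iterations,
                            seed=int(np.random.SeedSequence([config.seed, 777]).generate_state(1)[0] % 2**31))
    quadrats = landscape.frame.index
    rng = np.random.default_rng(null.seed)
    mats = dv.community_matrix(census_df, quadrats=quadrats, species=pool.species)
    alive = census_df[census_df["status"] == "alive"]
    out = {}
    for label in censuses_needed:
        mat = mats[label]
        if name in ("MPD", "MNTD"):
            block = dv._ses_block(mat, phylo.to_numpy(), pool.species, null, rng, sign_flip=False)
            out[label] = block[name]
        elif name in ("traitMPD", "traitMNTD"):
            block = dv._ses_block(mat, dendro.to_numpy(), pool.species, null, rng, sign_flip=True)
            out[label] = block["MPD" if name == "traitMPD" else "MNTD"]
        elif name in ("FDis", "RaoQ"):
            vals = [dv.functional_dispersion(row, gower.to_numpy()) for row in mat.to_numpy()]
            out[label] = pd.Series([v[0 if name == "FDis" else 1] for v in vals], index=mat.index)
        elif name in ("H", "D", "J"):
            pos = {"H": 0, "D": 1, "J": 2}[name]
            out[label] = pd.Series([dv.taxonomic_indices(row)[pos] for row in mat.to_numpy()],
                                   index=mat.index)
        elif name in ("SD", "CV_DBH"):
            grp = alive[alive["census"] == label].groupby("quadrat")["dbh_cm"]
            vals = pd.DataFrame([dv.structural_indices(g.to_numpy()) for _, g in grp],
                                index=[q for q, _ in grp], columns=["SD", "CV_DBH"]).reindex(quadrats)
            vals["SD"] = vals["SD"].fillna(0)
            out[label] = vals[name].astype(float)
        else:  # pragma: no cover - guarded upstream
            raise InvalidConfigurationError(f"unsupported covariate {name}")
    return out


def _embed_effects(census_df, pool, landscape, config, rng):
    """Rescale stem biomass so quadrat ΔAGB follows the configured linear model.

    For each interval, the target ΔAGB is Σ beta_i * x_i + N(0, noise_sd),
    with x_i the realized covariates on their raw scale — in embedded
    mode this linear model *is* the ΔAGB data-generating process,
    replacing the demographic ΔAGB signal. Stems of the interval's later
    census are rescaled uniformly within each quadrat; scales propagate
    to later censuses.
    """
    supported = _supported_covariates()
    for nm, _ in config.embedded_effects:
        if nm not in supported:
            raise InvalidConfigurationError(
                f"embedded covariate {nm!r} is not produced by the pipeline")
    pool_c = pool
    if pool_c.traits["wd"].isna().any():
        from .biomass import impute_wood_density
        pool_c = impute_wood_density(pool_c)
    trait_covs = {"traitMPD", "traitMNTD", "FDis", "RaoQ",
                  "ctraitMPD", "ctraitMNTD", "cFDis", "cRaoQ"}
    need_traits = any(nm in trait_covs for nm, _ in config.embedded_effects)
    phylo = phylo_distance_matrix(pool.tree).loc[pool.species, pool.species] if pool.tree is not None else None
    dendro = gower = None
    if need_traits:
        dendro, gower = dv.trait_dendrogram(pool_c)

    quadrats = landscape.frame.index
    censuses = sorted(census_df["census"].unique())
    truth = {"coefficients": dict(config.embedded_effects), "noise_sd": config.noise_sd,
             "intervals": {}}

    # cache realized index values per (base index, census)
    cache: dict = {}

    def base_values(base, label):
        if (base, label) not in cache:
            vals = _realized_index(base, [label], census_df, pool_c, landscape, config,
                                   phylo, dendro, gower)
            cache[(base, label)] = vals[label]
        return cache[(base, label)]

    for i, (c1, c2) in enumerate(zip(censuses[:-1], censuses[1:])):
        agb = quadrat_agb(census_df, pool_c, config.quadrat_side**2, quadrats=quadrats)
        delta_pre = agb[c2] - agb[c1]
        xs = {}
        for nm, beta in config.embedded_effects:
            if nm in ("elevation", "slope", "aspect", "convexity"):
                xs[nm] = landscape.frame[nm].astype(float)
            elif nm.startswith("c") and nm[1:] in dv.INDEX_NAMES:
                xs[nm] = base_values(nm[1:], c2) - base_values(nm[1:], c1)
            else:
                xs[nm] = base_values(nm, c1)
        target = pd.Series(0.0, index=quadrats, dtype=float)
        for nm, beta in config.embedded_effects:
            target = target + beta * xs[nm].reindex(quadrats).fillna(xs[nm].mean())
        if config.noise_sd > 0:
            target = target + rng.normal(0.0, config.noise_sd, len(target))

        goal_agb = agb[c1] + target
        cur = agb[c2]
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = (goal_agb / cur).to_numpy()
        bad = ~np.isfinite(factor) | (factor <= 0)
        if bad.any():
            log.warning("interval %s-%s: %d quadrats could not reach the embedded ΔAGB target",
                        c1, c2, int(bad.sum()))
            factor[bad] = 1.0
        fmap = pd.Series(factor, index=quadrats)
        for label in censuses:
            if label >= c2:
                sel = (census_df["census"] == label) & (census_df["status"] == "alive")
                census_df.loc[sel, "agb_scale"] = (
                    census_df.loc[sel, "agb_scale"].to_numpy()
                    * fmap.reindex(census_df.loc[sel, "quadrat"]).to_numpy()
                )
        truth["intervals"][f"{c1}-{c2}"] = {
            "intercept": 0.0,
            "mean_delta_before_adjustment": float(delta_pre.mean()),
            "covariates": {nm: {q: float(v) for q, v in xs[nm].items()} for nm in xs},
            "target_delta_agb": {q: float(v) for q, v in target.items()},
        }
    return census_df, truth


def simulate_census_series(pool: SpeciesPool, landscape: Landscape,
                           config: SimulationConfig) -> SyntheticStudy:
    """Full census series with growth, disturbance mortality and recruitment.

    Census 1 populates quadrats by habitat-filtered, dominance-structured
    species abundances; later censuses follow the demographic rules. A
    stem that dies in an interval appears once, flagged dead, in the
    census closing that interval.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    c1, aff, counter = _initial_census(pool, landscape, config, rng)
    all_census = [c1]
    current = c1
    for interval in range(config.n_censuses - 1):
        nxt, counter = _advance_census(current, interval, pool, landscape, config, rng,
                                       aff, counter)
        all_census.append(nxt)
        current = nxt[nxt["status"] == "alive"]
    censuses = pd.concat(all_census, ignore_index=True)
    censuses["agb_scale"] = 1.0  # embedding below may adjust per interval

    truth = {"coefficients": {}, "noise_sd": config.noise_sd, "intervals": {}}
    if config.embedded_effects:
        erng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
        censuses, truth = _embed_effects(censuses, pool, landscape, config, erng)
    return SyntheticStudy(pool, censuses, landscape, truth, config)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Convenience wrapper: pool + landscape + censuses from one config."""
    pool = simulate_species_pool(config.n_species, config.seed,
                                 config.wd_missing_fraction, config.fitted_height_fraction)
    landscape = simulate_landscape(config)
    return simulate_census_series(pool, landscape, config)
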