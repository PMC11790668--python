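"""Allometric aboveground-biomass (AGB) estimation from DBH censuses.

Stem AGB follows the two-step allometry standard for Chinese subtropical
plots: tree height from a species-specific power law

    H = a * D**b * CF          (D in cm, H in m, CF a back-transform correction)

and stem biomass from the improved pan-tropical equation

    AGB_kg = 0.0673 * (WD * D**2 * H) ** 0.976   (WD in g cm^-3)

Species without fitted height coefficients fall back to a pooled
all-species set; species without measured wood density are imputed from
congeners, then confamilials, then the pool mean (see
:func:`impute_wood_density`).

Quadrat-level AGB is expressed as Mg ha^-1 over the quadrat area
(default 400 m^2, i.e. a 20 m x 20 m cell); ``delta_agb`` takes
later-minus-earlier differences between censuses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UnknownSpeciesError, ValidationError

log = logging.getLogger(__name__)

AGB_COEF = 0.0673
AGB_EXP = 0.976

#: census-table columns expected by this module
CENSUS_COLUMNS = ["tree_id", "stem_id", "species", "quadrat", "dbh_cm", "census", "status"]


@dataclass
class SpeciesPool:
    """Per-species traits, taxonomy and allometry coefficients.

    ``traits`` is indexed by species id with columns
    ``genus, family, wd, hmax, life_form, a, b, cf, region``
    (``a/b/cf`` may be NaN → pooled coefficients are used;
    ``wd`` may be NaN before imputation). ``pooled_height`` is the
    all-species (a, b, CF) triple. ``tree`` optionally holds the
    phylogeny as a :class:`dendropy.Tree` whose taxon labels are
    species ids.
    """

    traits: pd.DataFrame
    pooled_height: tuple[float, float, float] = (2.0, 0.55, 1.0)
    tree: object | None = None
    #: imputation provenance per species: observed / genus / family / pool
    wd_source: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ("genus", "family", "wd", "hmax", "life_form") if c not in self.traits.columns]
        if missing:
            raise ValidationError(f"species table missing columns: {missing}")
        wd = self.traits["wd"].dropna()
        if (wd <= 0).any():
            raise ValidationError("wood density must be positive where present")

    @property
    def species(self) -> pd.Index:
        return self.traits.index

    def height_coefficients(self, species: str) -> tuple[float, float, float, bool]:
        """Return (a, b, cf, pooled?) for one species."""
        row = self.traits.loc[species]
        a, b = row.get("a", np.nan), row.get("b", np.nan)
        cf = row.get("cf", np.nan)
        if pd.isna(a) or pd.isna(b):
            return (*self.pooled_height, True)
        if pd.isna(cf):
            cf = 1.0  # CF not tabulated -> neutral correction
        return float(a), float(b), float(cf), False


def estimate_height(dbh_cm, a, b, cf=1.0):
    """Tree height (m) from the power-law allometry ``a * D**b * CF``.

    Accepts scalars or arrays; all inputs must be positive.
    """
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh_cm <= 0) or a <= 0 or b <= 0 or cf <= 0:
        raise ValueError("estimate_height requires strictly positive D, a, b, CF")
    out = a * dbh_cm**b * cf
    return float(out) if out.ndim == 0 else out


def estimate_stem_agb(dbh_cm, wd, height_m):
    """Stem aboveground biomass (kg) from DBH (cm), wood density (g/cm^3), height (m)."""
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    wd = np.asarray(wd, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(dbh_cm <= 0) or np.any(wd <= 0) or np.any(height_m <= 0):
        raise ValueError("estimate_stem_agb requires strictly positive D, WD, H")
    out = AGB_COEF * (wd * dbh_cm**2 * height_m) ** AGB_EXP
    return float(out) if out.ndim == 0 else out


def impute_wood_density(pool: SpeciesPool) -> SpeciesPool:
    """Fill missing wood densities hierarchically.

    Order of preference for a species with missing WD: mean over congeners
    with observed WD in the same climate region; else mean over
    confamilials (same region); else the pool-wide observed mean (logged
    as a fallback). Returns a new pool whose ``wd_source`` flags each
    species as observed/genus/family/pool.
    """
    traits = pool.traits.copy()
    if traits.empty:
        raise ValidationError("cannot impute wood density on an empty species pool")
    observed = traits["wd"].notna()
    if not observed.any():
        raise ValidationError("no observed wood density anywhere in the pool")
    region = traits["region"] if "region" in traits.columns else pd.Series("all", index=traits.index)

    source = pd.Series("observed", index=traits.index, name="wd_source")
    obs = traits.loc[observed]
    obs_region = region.loc[observed]
    pool_mean = float(obs["wd"].mean())

    for sp in traits.index[~observed]:
        gen, fam, reg = traits.at[sp, "genus"], traits.at[sp, "family"], region.at[sp]
        congeners = obs.loc[(obs["genus"] == gen) & (obs_region == reg), "wd"]
        if len(congeners):
            traits.at[sp, "wd"] = float(congeners.mean())
            source.at[sp] = "genus"
            continue
        confam = obs.loc[(obs["family"] == fam) & (obs_region == reg), "wd"]
        if len(confam):
            traits.at[sp, "wd"] = float(confam.mean())
            source.at[sp] = "family"
            continue
        traits.at[sp, "wd"] = pool_mean
        source.at[sp] = "pool"
        log.warning("species %s: no congener or confamilial WD; pool-wide mean %.3f used", sp, pool_mean)

    n_imp = int((source != "observed").sum())
    if n_imp:
        log.info("imputed wood density for %d/%d species (genus=%d, family=%d, pool=%d)",
                 n_imp, len(traits), (source == "genus").sum(), (source == "family").sum(),
                 (source == "pool").sum())
    return SpeciesPool(traits, pool.pooled_height, pool.tree, wd_source=source)


def stem_agb(census: pd.DataFrame, pool: SpeciesPool) -> pd.Series:
    """Per-record AGB (kg) for alive stems; dead stems contribute 0.

    Honors an optional ``agb_scale`` census column (per-stem multiplier,
    default 1) representing stem-level allometric variation not captured
    by DBH.
    """
    unknown = set(census["species"].unique()) - set(pool.species)
    if unknown:
        raise UnknownSpeciesError(unknown)
    traits = pool.traits
    if traits["wd"].isna().any():
        raise ValidationError("species pool has missing wood density; run impute_wood_density first")

    alive = census["status"].to_numpy() == "alive"
    d = census["dbh_cm"].to_numpy(dtype=float)
    sp = census["species"].to_numpy()

    # species-level coefficient lookup (pooled fallback where a/b missing)
    a = traits["a"].reindex(census["species"]).to_numpy(dtype=float) if "a" in traits else np.full(len(census), np.nan)
    b = traits["b"].reindex(census["species"]).to_numpy(dtype=float) if "b" in traits else np.full(len(census), np.nan)
    cf = traits["cf"].reindex(census["species"]).to_numpy(dtype=float) if "cf" in traits else np.full(len(census), np.nan)
    pooled = np.isnan(a) | np.isnan(b)
    pa, pb, pcf = pool.pooled_height
    a = np.where(pooled, pa, a)
    b = np.where(pooled, pb, b)
    cf = np.where(np.isnan(cf), np.where(pooled, pcf, 1.0), cf)
    n_pooled = int(np.isin(sp[pooled & alive], list(pool.species)).sum())
    if n_pooled:
        log.debug("pooled height coefficients used for %d stem records", n_pooled)

    wd = traits["wd"].reindex(census["species"]).to_numpy(dtype=float)
    agb = np.zeros(len(census))
    ok = alive & (d > 0)
    h = a[ok] * d[ok] ** b[ok] * cf[ok]
    agb[ok] = AGB_COEF * (wd[ok] * d[ok] ** 2 * h) ** AGB_EXP
    if "agb_scale" in census.columns:
        agb *= census["agb_scale"].fillna(1.0).to_numpy(dtype=float)
    return pd.Series(agb, index=census.index, name="agb_kg")


def quadrat_agb(
    census: pd.DataFrame,
    pool: SpeciesPool,
    quadrat_area: float = 400.0,
    quadrats: Sequence | None = None,
) -> pd.DataFrame:
    """Quadrat x census AGB density (Mg ha^-1).

    Sums stem AGB (kg) over alive stems per quadrat and census — every
    tagged stem of a multi-stemmed tree counts — then converts with
    kg→Mg (/1000) and m^2→ha (*10000/area), i.e. a factor 10/area.
    ``quadrats`` optionally lists all analysed quadrats so that empty
    ones appear with AGB 0.
    """
    if quadrat_area <= 0:
        raise ValueError("quadrat_area must be positive")
    df = census.assign(agb_kg=stem_agb(census, pool))
    tab = df.groupby(["quadrat", "census"], sort=True)["agb_kg"].sum().unstack("census", fill_value=0.0)
    if quadrats is not None:
        tab = tab.reindex(pd.Index(quadrats, name="quadrat"), fill_value=0.0)
    tab = tab * (10.0 / quadrat_area)  # kg per quadrat -> Mg per ha
    tab.columns.name = "census"
    return tab


def delta_agb(agb: pd.DataFrame, census_pairs: Iterable[tuple] | None = None) -> pd.DataFrame:
    """Per-quadrat ΔAGB (Mg ha^-1), later minus earlier, one column per interval.

    ``census_pairs`` defaults to consecutive censuses in column order.
    Columns are labelled ``"<c1>-<c2>"``.
    """
    if census_pairs is None:
        cols = list(agb.columns)
        census_pairs = list(zip(cols[:-1], cols[1:]))
    out = {}
    for c1, c2 in census_pairs:
        for c in (c1, c2):
            if c not in agb.columns:
                raise KeyError(f"census {c!r} absent from AGB table")
        if agb[[c1, c2]].isna().any().any():
            bad = agb.index[agb[[c1, c2]].isna().any(axis=1)].tolist()
            raise ValidationError(f"quadrats missing AGB in interval {c1}->{c2}: {bad[:5]}")
        out[f"{c1}-{c2}"] = agb[c2] - agb[c1]
    res = pd.DataFrame(out, index=agb.index)
    res.columns.name = "interval"
    return res
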