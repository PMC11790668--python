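"""Quadrat-level diversity across four dimensions, with null-model SES.

Eleven indices per quadrat and census:

* taxonomic — Shannon–Wiener ``H = -Σ p_i ln p_i``, Gini–Simpson
  ``D = 1 - Σ p_i**2``, Pielou evenness ``J = H / ln S``;
* structural — stand density ``SD`` (stems with DBH ≥ 1 cm) and the DBH
  coefficient of variation ``CV_DBH = σ/μ`` (sample sd);
* phylogenetic — ``MPD`` and ``MNTD`` as standardized effect sizes
  (observed − null mean)/null sd on the phylogeny's cophenetic distances;
* functional — ``traitMPD``/``traitMNTD`` (SES on trait-dendrogram
  cophenetic distances, multiplied by −1 so that larger values mean
  greater trait divergence in the conventional reading), plus functional
  dispersion ``FDis`` and Rao's quadratic entropy ``RaoQ`` on the raw
  Gower trait dissimilarity.

The default null model is the taxa shuffle: community richness is held
fixed and species identities are drawn uniformly without replacement from
the pool, i.e. labels are permuted on the distance matrix. An
occupancy-preserving independent-swap randomization of the whole
community matrix is available as an alternative scheme.

Change values (``cH`` … ``cRaoQ``) are later-minus-earlier differences
between censuses; missing values propagate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .biomass import SpeciesPool
from .errors import InvalidConfigurationError, ValidationError

log = logging.getLogger(__name__)

INDEX_NAMES = ["H", "D", "J", "SD", "CV_DBH", "MPD", "MNTD",
               "traitMPD", "traitMNTD", "FDis", "RaoQ"]


@dataclass(frozen=True)
class NullModelSpec:
    """Randomization scheme for SES metrics."""

    scheme: str = "taxa-shuffle"
    n_iterations: int = 999
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 2:
            raise InvalidConfigurationError("null model needs n_iterations >= 2")
        if self.scheme not in ("taxa-shuffle", "independent-swap"):
            raise InvalidConfigurationError(f"unknown null scheme {self.scheme!r}")


# ---------------------------------------------------------------------------
# scalar indices


def taxonomic_indices(abundances, gini: bool = True) -> tuple[float, float, float]:
    """Shannon H, Simpson D and Pielou J from species counts.

    ``gini=True`` (default) reports the Gini–Simpson form 1 − Σp², a
    diversity; ``gini=False`` reports the dominance form Σp². An empty
    community yields (nan, nan, nan); a monoculture yields (0, ·, nan) —
    evenness is undefined for a single species.
    """
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    n = x.sum()
    if n == 0:
        return (np.nan, np.nan, np.nan)
    p = x / n
    h = float(-(p * np.log(p)).sum())
    d = float(1.0 - (p**2).sum()) if gini else float((p**2).sum())
    s = len(p)
    j = h / np.log(s) if s > 1 else np.nan
    return (h, d, j)


def structural_indices(dbh_values) -> tuple[int, float]:
    """Stand density (stem count) and CV of DBH (sample sd / mean).

    CV is NaN with fewer than 2 stems.
    """
    d = np.asarray(dbh_values, dtype=float)
    sd_count = int(len(d))
    if sd_count < 2:
        return (sd_count, np.nan)
    return (sd_count, float(np.std(d, ddof=1) / np.mean(d)))


# ---------------------------------------------------------------------------
# distance-based metrics


def raw_mpd(dist: np.ndarray, weights=None) -> float:
    """Mean pairwise distance over distinct pairs of a community submatrix.

    With ``weights`` (relative abundances) pairs are weighted by
    ``p_i * p_j`` over i ≠ j.
    """
    k = dist.shape[0]
    if k < 2:
        return np.nan
    if weights is None:
        iu = np.triu_indices(k, 1)
        return float(dist[iu].mean())
    p = np.asarray(weights, float)
    w = np.outer(p, p)
    np.fill_diagonal(w, 0.0)
    return float((w * dist).sum() / w.sum())


def raw_mntd(dist: np.ndarray, weights=None) -> float:
    """Mean (optionally abundance-weighted) distance to the nearest other member."""
    k = dist.shape[0]
    if k < 2:
        return np.nan
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    mins = d.min(axis=1)
    if weights is None:
        return float(mins.mean())
    p = np.asarray(weights, float)
    return float((p * mins).sum() / p.sum())


def _null_draws(n_pool: int, k: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """m random k-subsets (as index arrays) of range(n_pool), taxa-shuffle."""
    return np.argsort(rng.random((m, n_pool)), axis=1)[:, :k]


def _null_metrics(dmat: np.ndarray, idx: np.ndarray, weights=None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized raw MPD and MNTD for each row of community indices.

    ``weights`` fixes the community abundance vector while species
    identities are shuffled (abundance-weighted null).
    """
    sub = dmat[idx[:, :, None], idx[:, None, :]]
    k = idx.shape[1]
    big = sub + np.eye(k) * (dmat.max() + 1.0) * 2
    mins = big.min(axis=2)
    if weights is None:
        mpd = sub.sum(axis=(1, 2)) / (k * (k - 1))
        mntd = mins.mean(axis=1)
    else:
        p = np.asarray(weights, float)
        w = np.outer(p, p)
        np.fill_diagonal(w, 0.0)
        mpd = (sub * w).sum(axis=(1, 2)) / w.sum()
        mntd = (mins * p).sum(axis=1) / p.sum()
    return mpd, mntd


def ses_metric(
    community,
    dist: pd.DataFrame,
    metric: str = "MPD",
    null: NullModelSpec | None = None,
    sign_flip: bool = False,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
    abundances=None,
) -> float:
    """Standardized effect size of MPD or MNTD under the taxa-shuffle null.

    ``community`` is an iterable of species labels present in ``dist``;
    passing ``abundances`` (same order) switches to the
    abundance-weighted raw metrics, with abundances held fixed while
    species identities are shuffled.
    SES = (observed − mean(null)) / sd(null); the null sd uses the sample
    (n−1) convention over Monte-Carlo draws. With ``exhaustive=True`` all
    C(pool, richness) subsets are enumerated instead and the sd of that
    complete null distribution (population form) is used. ``sign_flip``
    multiplies the SES by −1 (trait-metric convention). Returns NaN for
    richness < 2 or a degenerate null (sd 0).
    """
    if metric not in ("MPD", "MNTD"):
        raise InvalidConfigurationError(f"metric must be MPD or MNTD, got {metric!r}")
    species = list(dict.fromkeys(community))
    missing = [s for s in species if s not in dist.index]
    if missing:
        raise KeyError(f"species absent from distance matrix: {missing[:5]}")
    k = len(species)
    if k < 2:
        return np.nan
    dmat = dist.to_numpy(dtype=float)
    pos = dist.index.get_indexer(species)
    w = None if abundances is None else np.asarray(abundances, float)
    obs_sub = dmat[np.ix_(pos, pos)]
    obs = raw_mpd(obs_sub, w) if metric == "MPD" else raw_mntd(obs_sub, w)

    n_pool = len(dist)
    if exhaustive:
        vals = []
        for comb in itertools.combinations(range(n_pool), k):
            sub = dmat[np.ix_(comb, comb)]
            vals.append(raw_mpd(sub, w) if metric == "MPD" else raw_mntd(sub, w))
        vals = np.asarray(vals)
        mu, sd = vals.mean(), vals.std(ddof=0)
    else:
        null = null or NullModelSpec()
        if rng is None:
            rng = np.random.default_rng(null.seed)
        idx = _null_draws(n_pool, k, null.n_iterations, rng)
        mpd_null, mntd_null = _null_metrics(dmat, idx, weights=w)
        vals = mpd_null if metric == "MPD" else mntd_null
        mu, sd = vals.mean(), vals.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        return np.nan
    ses = (obs - mu) / sd
    return float(-ses if sign_flip else ses)


# ---------------------------------------------------------------------------
# trait space


def gower_distance(pool: SpeciesPool) -> pd.DataFrame:
    """Equal-weight Gower dissimilarity over WD, maximum height, life form.

    Numeric traits are range-scaled over the full pool; life form
    contributes a 0/1 mismatch term.
    """
    t = pool.traits
    for c in ("wd", "hmax", "life_form"):
        if t[c].isna().any():
            bad = t.index[t[c].isna()].tolist()
            raise ValidationError(f"missing trait {c!r} for species {bad[:5]}")
    n = len(t)
    parts = []
    for c in ("wd", "hmax"):
        v = t[c].to_numpy(dtype=float)
        rng_ = v.max() - v.min()
        diff = np.abs(v[:, None] - v[None, :])
        parts.append(diff / rng_ if rng_ > 0 else np.zeros((n, n)))
    lf = t["life_form"].to_numpy()
    parts.append((lf[:, None] != lf[None, :]).astype(float))
    g = sum(parts) / 3.0
    np.fill_diagonal(g, 0.0)
    return pd.DataFrame(g, index=t.index, columns=t.index)


def trait_dendrogram(pool: SpeciesPool) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(cophenetic distances of the UPGMA trait dendrogram, raw Gower matrix).

    The dendrogram distances feed traitMPD/traitMNTD; the raw Gower
    matrix feeds FDis and RaoQ.
    """
    gower = gower_distance(pool)
    linkage = sch.average(squareform(gower.to_numpy(), checks=False))
    coph = squareform(sch.cophenet(linkage))
    return pd.DataFrame(coph, index=gower.index, columns=gower.index), gower


def functional_dispersion(abundances, dist: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """(FDis, RaoQ) from abundances and a species dissimilarity matrix.

    RaoQ = Σ_i Σ_j p_i p_j d_ij. FDis is the abundance-weighted mean
    distance of species to the abundance-weighted centroid in the
    principal-coordinate embedding of the dissimilarity matrix, negative
    eigenvalues truncated.
    """
    p = np.asarray(abundances, dtype=float)
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    if p.sum() <= 0:
        return (np.nan, np.nan)
    keep = p > 0
    p = p[keep] / p[keep].sum()
    d = d[np.ix_(keep, keep)]
    raoq = float(p @ d @ p)
    k = len(p)
    if k == 1:
        return (0.0, 0.0)
    # classical MDS / PCoA with truncation of negative eigenvalues
    a = -0.5 * d**2
    j = np.eye(k) - np.ones((k, k)) / k
    b = j @ a @ j
    w, v = np.linalg.eigh((b + b.T) / 2)
    posit = w > max(w.max(), 0) * 1e-10
    if not posit.any():
        return (0.0, raoq)
    coords = v[:, posit] * np.sqrt(w[posit])
    centroid = p @ coords
    fdis = float(p @ np.linalg.norm(coords - centroid, axis=1))
    return (fdis, raoq)


# ---------------------------------------------------------------------------
# community matrices and profiles


def community_matrix(census: pd.DataFrame, quadrats=None, species=None) -> dict:
    """Per-census quadrat x species abundance matrices (alive stems only).

    Returns {census label: DataFrame}. Individuals are counted at the
    tree level (multi-stem trees count once).
    """
    alive = census[census["status"] == "alive"]
    trees = alive.drop_duplicates(subset=["tree_id", "census"])
    out = {}
    for label, grp in trees.groupby("census", sort=True):
        mat = pd.crosstab(grp["quadrat"], grp["species"])
        if quadrats is not None:
            mat = mat.reindex(pd.Index(quadrats, name="quadrat"), fill_value=0)
        if species is not None:
            mat = mat.reindex(columns=pd.Index(species, name="species"), fill_value=0)
        out[label] = mat
    return out


def independent_swap(matrix: pd.DataFrame, rng: np.random.Generator, n_swaps: int | None = None) -> pd.DataFrame:
    """Occupancy- and richness-preserving randomization of a presence matrix.

    Repeatedly finds 2x2 checkerboard submatrices in the incidence
    (presence/absence) matrix and swaps them, preserving row and column
    totals. Used by the "independent-swap" null scheme.
    """
    inc = (matrix.to_numpy() > 0).astype(np.int8)
    nr, nc = inc.shape
    n_swaps = n_swaps or 5 * nr * nc
    done = 0
    attempts = 0
    while done < n_swaps and attempts < 20 * n_swaps:
        attempts += 1
        r = rng.integers(0, nr, size=2)
        c = rng.integers(0, nc, size=2)
        if r[0] == r[1] or c[0] == c[1]:
            continue
        sub = inc[np.ix_(r, c)]
        if sub[0, 0] == sub[1, 1] and sub[0, 1] == sub[1, 0] and sub[0, 0] != sub[0, 1]:
            inc[np.ix_(r, c)] = sub[::-1]
            done += 1
    return pd.DataFrame(inc, index=matrix.index, columns=matrix.columns)


def _ses_block(
    mat: pd.DataFrame,
    dmat: np.ndarray,
    species_order: pd.Index,
    null: NullModelSpec,
    rng: np.random.Generator,
    sign_flip: bool,
    abundance_weighted: bool = False,
) -> pd.DataFrame:
    """SES MPD and MNTD for every quadrat row of one community matrix."""
    cols = mat.reindex(columns=species_order, fill_value=0).to_numpy()
    n_pool = len(species_order)
    out = np.full((len(mat), 2), np.nan)

    if null.scheme == "independent-swap":
        presence = pd.DataFrame((cols > 0).astype(int), index=mat.index, columns=species_order)
        obs = np.full((len(mat), 2), np.nan)
        for i in range(len(mat)):
            pos = np.flatnonzero(cols[i])
            if len(pos) < 2:
                continue
            sub = dmat[np.ix_(pos, pos)]
            obs[i] = (raw_mpd(sub), raw_mntd(sub))
        nulls = np.full((null.n_iterations, len(mat), 2), np.nan)
        for it in range(null.n_iterations):
            sw = independent_swap(presence, rng).to_numpy()
            for i in range(len(mat)):
                pos = np.flatnonzero(sw[i])
                if len(pos) < 2:
                    continue
                sub = dmat[np.ix_(pos, pos)]
                nulls[it, i] = (raw_mpd(sub), raw_mntd(sub))
        mu = np.nanmean(nulls, axis=0)
        sd = np.nanstd(nulls, axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (obs - mu) / sd
        out[~np.isfinite(out)] = np.nan
    else:
        for i in range(len(mat)):
            pos = np.flatnonzero(cols[i])
            k = len(pos)
            if k < 2 or k > n_pool:
                continue
            if k == n_pool and not abundance_weighted:
                # saturated communities have a degenerate presence-based null
                log.debug("quadrat %s saturates the pool; SES degenerate", mat.index[i])
                continue
            w = cols[i][pos].astype(float) if abundance_weighted else None
            sub = dmat[np.ix_(pos, pos)]
            idx = _null_draws(n_pool, k, null.n_iterations, rng)
            mpd_null, mntd_null = _null_metrics(dmat, idx, weights=w)
            for jcol, (observed, vals) in enumerate(
                [(raw_mpd(sub, w), mpd_null), (raw_mntd(sub, w), mntd_null)]
            ):
                s = vals.std(ddof=1)
                if s > 0:
                    out[i, jcol] = (observed - vals.mean()) / s
    if sign_flip:
        out = -out
    return pd.DataFrame(out, index=mat.index, columns=["MPD", "MNTD"])


def diversity_profile(
    census: pd.DataFrame,
    pool: SpeciesPool,
    phylo_dist: pd.DataFrame,
    dendro_dist: pd.DataFrame,
    gower: pd.DataFrame,
    null: NullModelSpec | None = None,
    quadrats=None,
    abundance_weighted: bool = False,
    gini: bool = True,
) -> pd.DataFrame:
    """All eleven indices per quadrat and census (long layout).

    Null randomizations are drawn from a single generator seeded by the
    null spec, with censuses and quadrats visited in sorted order, so a
    given input and spec always yields identical output.
    """
    null = null or NullModelSpec()
    rng = np.random.default_rng(null.seed)
    species_order = pool.species
    mats = community_matrix(census, quadrats=quadrats, species=species_order)
    alive = census[census["status"] == "alive"]

    frames = []
    for label in sorted(mats):
        mat = mats[label]
        counts = mat.to_numpy()
        tax = np.array([taxonomic_indices(row, gini=gini) for row in counts])
        dbh = alive[alive["census"] == label].groupby("quadrat")["dbh_cm"]
        struct = pd.DataFrame(
            [structural_indices(g.to_numpy()) for _, g in dbh],
            index=[q for q, _ in dbh], columns=["SD", "CV_DBH"],
        ).reindex(mat.index)
        struct["SD"] = struct["SD"].fillna(0).astype(float)

        phylo = _ses_block(mat, phylo_dist.reindex(index=species_order, columns=species_order).to_numpy(),
                           species_order, null, rng, sign_flip=False,
                           abundance_weighted=abundance_weighted)
        trait = _ses_block(mat, dendro_dist.reindex(index=species_order, columns=species_order).to_numpy(),
                           species_order, null, rng, sign_flip=True,
                           abundance_weighted=abundance_weighted)

        gmat = gower.reindex(index=species_order, columns=species_order).to_numpy()
        fd = np.array([functional_dispersion(row, gmat) if row.sum() > 0 else (np.nan, np.nan)
                       for row in counts])

        block = pd.DataFrame(
            {
                "H": tax[:, 0], "D": tax[:, 1], "J": tax[:, 2],
                "SD": struct["SD"].to_numpy(), "CV_DBH": struct["CV_DBH"].to_numpy(),
                "MPD": phylo["MPD"].to_numpy(), "MNTD": phylo["MNTD"].to_numpy(),
                "traitMPD": trait["MPD"].to_numpy(), "traitMNTD": trait["MNTD"].to_numpy(),
                "FDis": fd[:, 0], "RaoQ": fd[:, 1],
            },
            index=mat.index,
        )
        block.insert(0, "census", label)
        frames.append(block.reset_index())
    return pd.concat(frames, ignore_index=True)


def change_values(profile: pd.DataFrame, census_pairs=None) -> pd.DataFrame:
    """Later-minus-earlier change of every index between census pairs.

    Missing values propagate to missing and are counted in the log.
    Columns are the indices prefixed with "c"; rows are quadrat x interval.
    """
    wide = profile.set_index(["quadrat", "census"])
    censuses = sorted(profile["census"].unique())
    if census_pairs is None:
        census_pairs = list(zip(censuses[:-1], censuses[1:]))
    frames = []
    for c1, c2 in census_pairs:
        a = wide.xs(c1, level="census")[INDEX_NAMES]
        b = wide.xs(c2, level="census")[INDEX_NAMES]
        diff = (b - a).rename(columns={n: f"c{n}" for n in INDEX_NAMES})
        n_missing = int(diff.isna().sum().sum())
        if n_missing:
            log.info("interval %s-%s: %d missing change values propagated", c1, c2, n_missing)
        diff.insert(0, "interval", f"{c1}-{c2}")
        frames.append(diff.reset_index())
    return pd.concat(frames, ignore_index=True)
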