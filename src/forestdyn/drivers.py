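"""Driver analysis of ΔAGB: rank tests, collinearity filtering, model
selection and variance partitioning.

For each time interval and habitat stratum the per-quadrat ΔAGB is
regressed on z-scored covariates — four topographic variables plus the
eleven diversity indices at the interval's first census and their change
values. The chain is:

1. ``standardize`` — centre/scale all variables (zero-variance columns
   dropped);
2. ``vif_filter`` — iteratively remove the predictor with the largest
   variance inflation factor until all VIF ≤ 5;
3. ``best_subset_aic`` — exhaustive lowest-AIC Gaussian (identity link)
   model over all non-empty predictor subsets, with a stepwise fallback
   above ``max_exhaustive`` predictors;
4. ``hierarchical_partition`` — Chevan–Sutherland decomposition of the
   selected model's R² into per-predictor independent contributions;
5. ``dimension_importance`` — contributions summed into the taxonomic /
   structural / phylogenetic / functional / topographic dimensions.

AGB levels across censuses are compared with the two-sided Wilcoxon
rank-sum (Mann–Whitney) test per stratum.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .diversity import INDEX_NAMES
from .errors import InvalidConfigurationError, ValidationError

log = logging.getLogger(__name__)

TOPO_VARS = ["elevation", "slope", "aspect", "convexity"]

#: base variable -> diversity dimension; change values ("c" prefix) map identically
DIMENSION_MAP = {
    "H": "taxonomic", "D": "taxonomic", "J": "taxonomic",
    "SD": "structural", "CV_DBH": "structural",
    "MPD": "phylogenetic", "MNTD": "phylogenetic",
    "traitMPD": "functional", "traitMNTD": "functional",
    "FDis": "functional", "RaoQ": "functional",
    "elevation": "topographic", "slope": "topographic",
    "aspect": "topographic", "convexity": "topographic",
}


def predictor_dimension(name: str) -> str:
    """Dimension of a predictor; change values share their base's dimension."""
    if name in DIMENSION_MAP:
        return DIMENSION_MAP[name]
    if name.startswith("c") and name[1:] in DIMENSION_MAP:
        return DIMENSION_MAP[name[1:]]
    raise KeyError(f"predictor {name!r} maps to no diversity dimension")


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


# ---------------------------------------------------------------------------


def wilcoxon_compare(agb: pd.DataFrame, census_pairs=None, strata: pd.Series | None = None,
                     paired: bool = False) -> pd.DataFrame:
    """Two-sided rank test on per-quadrat AGB for each census pair and stratum.

    Default is the unpaired rank-sum (Mann–Whitney) with tie/continuity
    corrections via the normal approximation for larger samples (exact
    where SciPy can); ``paired=True`` switches to the signed-rank test on
    quadrat-wise differences.
    """
    if census_pairs is None:
        cols = list(agb.columns)
        census_pairs = list(zip(cols[:-1], cols[1:]))
    groups = {"whole": agb.index}
    if strata is not None:
        for h, idx in agb.index.to_series().groupby(strata.reindex(agb.index)):
            groups[h] = idx.index
    recs = []
    for name, idx in groups.items():
        if len(idx) == 0:
            raise ValidationError(f"stratum {name!r} has no quadrats")
        sub = agb.loc[idx]
        for c1, c2 in census_pairs:
            x, y = sub[c1].to_numpy(), sub[c2].to_numpy()
            if len(x) < 2:
                raise ValidationError(f"stratum {name!r} has <2 quadrats")
            if paired:
                res = stats.wilcoxon(x, y, alternative="two-sided", zero_method="wilcox")
            else:
                res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
            recs.append(dict(stratum=name, pair=f"{c1}-{c2}", statistic=float(res.statistic),
                             p_value=float(res.pvalue), stars=significance_stars(res.pvalue)))
    return pd.DataFrame.from_records(recs)


def standardize(frame: pd.DataFrame) -> pd.DataFrame:
    """z-score every column (mean 0, sample sd 1); drop zero-variance columns."""
    if len(frame) < 2:
        raise ValidationError("standardize needs at least 2 rows")
    out = {}
    for col in frame.columns:
        v = frame[col].to_numpy(dtype=float)
        sd = np.std(v, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            log.warning("dropping zero-variance column %r", col)
            continue
        out[col] = (v - v.mean()) / sd
    return pd.DataFrame(out, index=frame.index)


def _vif(x: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1 - R²) of x_j regressed on the other columns."""
    y = x[:, j]
    others = np.delete(x, j, axis=1)
    a = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return np.inf
    r2 = 1.0 - (resid**2).sum() / tss
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_filter(x: pd.DataFrame, threshold: float = 5.0) -> tuple[pd.DataFrame, list]:
    """Iteratively drop the worst-VIF predictor until all VIF ≤ threshold.

    Perfectly collinear predictors (infinite VIF) are removed first.
    Returns (reduced frame, [(dropped name, VIF at removal), ...]).
    """
    cols = list(x.columns)
    dropped = []
    while len(cols) >= 2:
        arr = x[cols].to_numpy(dtype=float)
        vifs = np.array([_vif(arr, j) for j in range(len(cols))])
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        dropped.append((cols[worst], float(vifs[worst])))
        log.info("VIF filter: dropping %r (VIF=%.2f)", cols[worst], vifs[worst])
        cols.pop(worst)
    return x[cols], dropped


def _rss(xmat: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(xmat, y, rcond=None)
    r = y - xmat @ beta
    return float(r @ r)


def gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC of a Gaussian OLS fit with k slope parameters.

    Uses the profile log-likelihood with estimated variance: intercept and
    the variance are counted, giving k + 2 parameters.
    """
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * (k + 2)


@dataclass
class SelectedModel:
    predictors: list
    aic: float
    r_squared: float
    n: int
    coefficients: pd.DataFrame  # index predictor (+const); columns coef, se, p_value, stars
    method: str = "exhaustive"
    aic_ties: int = 0


def _fit_ols(x: pd.DataFrame, y: pd.Series, predictors) -> sm.regression.linear_model.RegressionResultsWrapper:
    xmat = sm.add_constant(x[list(predictors)], has_constant="add")
    return sm.OLS(np.asarray(y, float), np.asarray(xmat, float)).fit()


def best_subset_aic(x: pd.DataFrame, y: pd.Series, max_exhaustive: int = 15) -> SelectedModel:
    """Lowest-AIC Gaussian GLM over non-empty predictor subsets.

    Exhaustive for up to ``max_exhaustive`` predictors, otherwise
    bidirectional stepwise from the empty model (logged). Ties are broken
    toward fewer predictors, then lexicographically. Subset size is capped
    at n − 3 so the variance remains estimable.
    """
    names = list(x.columns)
    n = len(x)
    if n < 4:
        raise ValidationError("best_subset_aic needs at least 4 observations")
    cap = min(len(names), n - 3)
    if cap < len(names):
        log.info("subset size capped at %d (< %d predictors) by sample size", cap, len(names))
    yv = y.to_numpy(dtype=float)
    ones = np.ones((n, 1))

    if len(names) <= max_exhaustive:
        method = "exhaustive"
        best = None
        ties = 0
        for k in range(1, cap + 1):
            for comb in itertools.combinations(names, k):
                xmat = np.column_stack([ones, x[list(comb)].to_numpy(dtype=float)])
                aic = gaussian_aic(_rss(xmat, yv), n, k)
                key = (aic, k, comb)
                if best is None or aic < best[0] - 1e-10:
                    best, ties = key, 0
                elif abs(aic - best[0]) <= 1e-10:
                    ties += 1
                    if (k, comb) < best[1:]:
                        best = key
        selected = list(best[2])
    else:
        method = "stepwise"
        log.info("%d predictors > max_exhaustive=%d; bidirectional stepwise AIC",
                 len(names), max_exhaustive)
        ties = 0
        current: list = []
        current_aic = np.inf
        improved = True
        while improved:
            improved = False
            candidates = []
            for nm in names:
                if nm not in current and len(current) < cap:
                    trial = current + [nm]
                    xmat = np.column_stack([ones, x[trial].to_numpy(dtype=float)])
                    candidates.append((gaussian_aic(_rss(xmat, yv), n, len(trial)), sorted(trial)))
            for nm in current:
                trial = [t for t in current if t != nm]
                if trial:
                    xmat = np.column_stack([ones, x[trial].to_numpy(dtype=float)])
                    candidates.append((gaussian_aic(_rss(xmat, yv), n, len(trial)), sorted(trial)))
            if candidates:
                candidates.sort(key=lambda c: (c[0], len(c[1]), tuple(c[1])))
                if candidates[0][0] < current_aic - 1e-10:
                    current_aic, current = candidates[0][0], candidates[0][1]
                    improved = True
        if not current:  # degenerate: take the best single predictor
            best1 = min(
                ((gaussian_aic(_rss(np.column_stack([ones, x[[nm]].to_numpy(float)]), yv), n, 1), nm)
                 for nm in names), key=lambda t: t[0])
            current = [best1[1]]
        selected = [nm for nm in names if nm in current]

    fit = _fit_ols(x, y, selected)
    coef = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p_value": fit.pvalues},
        index=["const"] + selected,
    )
    coef["stars"] = coef["p_value"].map(significance_stars)
    k = len(selected)
    aic = gaussian_aic(float(fit.ssr), n, k)
    return SelectedModel(selected, float(aic), float(fit.rsquared), n, coef, method, ties)


def _r2(x: pd.DataFrame, y: np.ndarray, subset: tuple) -> float:
    n = len(y)
    if not subset:
        return 0.0
    xmat = np.column_stack([np.ones(n), x[list(subset)].to_numpy(dtype=float)])
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    return 1.0 - _rss(xmat, y) / tss


def hierarchical_partition(x: pd.DataFrame, y: pd.Series, predictors=None) -> pd.DataFrame:
    """Independent contribution of each predictor to model R².

    Chevan–Sutherland hierarchical partitioning: the independent
    contribution I_j averages, over hierarchy levels h = 0..k−1, the mean
    R² increment of adding predictor j to each subset of size h that
    excludes it. Independent contributions sum to the full-model R².
    Returns a frame with I (independent), J (joint = marginal R² − I,
    may be negative) and relative importance in percent.
    """
    preds = list(predictors) if predictors is not None else list(x.columns)
    k = len(preds)
    if k < 1:
        raise InvalidConfigurationError("hierarchical partition needs >= 1 predictor")
    if k > 12:
        raise InvalidConfigurationError(
            f"{k} predictors would need 2^{k} model fits; select 12 or fewer")
    yv = y.to_numpy(dtype=float)
    r2 = {}
    for size in range(0, k + 1):
        for comb in itertools.combinations(preds, size):
            r2[frozenset(comb)] = _r2(x, yv, comb)
    indep = {}
    for p in preds:
        others = [q for q in preds if q != p]
        level_means = []
        for h in range(0, k):
            incs = [
                r2[frozenset(comb) | {p}] - r2[frozenset(comb)]
                for comb in itertools.combinations(others, h)
            ]
            level_means.append(np.mean(incs))
        indep[p] = float(np.mean(level_means))
    total = sum(indep.values())
    out = pd.DataFrame({"independent": indep})
    out["joint"] = [r2[frozenset([p])] - indep[p] for p in preds]
    out["relative_importance"] = (
        out["independent"] / total * 100.0 if total > 0 else np.nan
    )
    out.index.name = "predictor"
    return out


def dimension_importance(partition: pd.DataFrame, grouping=None) -> pd.Series:
    """Sum relative importances (%) into diversity dimensions."""
    if grouping is None:
        grouping = {p: predictor_dimension(p) for p in partition.index}
    missing = [p for p in partition.index if p not in grouping]
    if missing:
        raise KeyError(f"predictors without a dimension: {missing}")
    groups = pd.Series({p: grouping[p] for p in partition.index}, name="dimension")
    out = partition["relative_importance"].groupby(groups).sum()
    out.name = "relative_importance"
    return out


# ---------------------------------------------------------------------------


@dataclass
class DriverResult:
    """Everything reported for one interval x stratum model cell."""

    interval: str
    stratum: str
    n: int
    dropped_by_vif: list
    model: SelectedModel
    partition: pd.DataFrame
    dimensions: pd.Series
    note: str = ""

    def summary(self) -> dict:
        return {
            "interval": self.interval,
            "stratum": self.stratum,
            "n": self.n,
            "selected": self.model.predictors,
            "aic": self.model.aic,
            "r_squared": self.model.r_squared,
            "selection_method": self.model.method,
            "dropped_by_vif": [name for name, _ in self.dropped_by_vif],
            "dimension_importance": {k: float(v) for k, v in self.dimensions.items()},
        }


def build_model_frame(covariates: pd.DataFrame, interval: str, stratum: str = "whole") -> pd.DataFrame:
    """One interval x stratum slice with listwise deletion of missing cells.

    ``covariates`` is the pipeline's tidy table: one row per quadrat x
    interval, with ``delta_agb``, ``habitat``, topographic columns,
    initial indices and change values.
    """
    sub = covariates[covariates["interval"] == interval]
    if stratum != "whole":
        sub = sub[sub["habitat"] == stratum]
    cols = ["delta_agb"] + [c for c in sub.columns
                            if c not in ("quadrat", "interval", "habitat", "delta_agb")]
    frame = sub.set_index("quadrat")[cols].astype(float)
    before = len(frame)
    frame = frame.dropna()
    if len(frame) < before:
        log.info("%s/%s: %d quadrats dropped listwise for missing values",
                 interval, stratum, before - len(frame))
    return frame


def analyse_cell(frame: pd.DataFrame, vif_threshold: float = 5.0, max_exhaustive: int = 15,
                 max_partition: int = 12, interval: str = "", stratum: str = "") -> DriverResult:
    """standardize → VIF filter → best-subset AIC → partition, for one cell."""
    z = standardize(frame)
    if "delta_agb" not in z.columns:
        raise ValidationError("response delta_agb has zero variance in this cell")
    y = z["delta_agb"]
    x = z.drop(columns=["delta_agb"])
    x, dropped = vif_filter(x, vif_threshold)
    model = best_subset_aic(x, y, max_exhaustive=max_exhaustive)
    note = ""
    preds = model.predictors
    if len(preds) > max_partition:
        # partition the strongest max_partition predictors of the chosen model
        order = model.coefficients.loc[preds, "p_value"].sort_values().index
        preds = sorted(order[:max_partition], key=preds.index)
        note = f"partition restricted to {max_partition} of {len(model.predictors)} selected predictors"
        log.warning("%s/%s: %s", interval, stratum, note)
    part = hierarchical_partition(x, y, preds)
    dims = dimension_importance(part)
    return DriverResult(interval, stratum, len(frame), dropped, model, part, dims, note)


def run_driver_analysis(covariates: pd.DataFrame, strata=("whole", "H1", "H2", "H3"),
                        intervals=None, vif_threshold: float = 5.0,
                        max_exhaustive: int = 15, min_n: int = 10) -> list[DriverResult]:
    """One DriverResult per interval x stratum; small strata are skipped."""
    if intervals is None:
        intervals = sorted(covariates["interval"].unique())
    results = []
    for interval in intervals:
        for stratum in strata:
            frame = build_model_frame(covariates, interval, stratum)
            if len(frame) < min_n:
                log.warning("skipping %s/%s: only %d quadrats (min %d)",
                            interval, stratum, len(frame), min_n)
                continue
            results.append(analyse_cell(frame, vif_threshold, max_exhaustive,
                                        interval=interval, stratum=stratum))
    return results
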