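"""Quadrat-level topography from a corner-elevation grid, plus habitat labels.

The plot is a ``cols x rows`` lattice of square quadrats; elevations are
surveyed at the ``(cols+1) x (rows+1)`` grid of quadrat corners. Following
the convention long used for stem-mapped forest-dynamics plots:

* **elevation** — mean of the quadrat's four corner elevations;
* **slope** — mean angular slope (degrees) of the four planes obtained by
  omitting each corner in turn;
* **aspect** — compass direction (degrees clockwise from north, [0, 360))
  of steepest descent of the least-squares plane through the four corners;
* **convexity** — quadrat elevation minus the mean elevation of its (up to
  eight) neighbouring quadrats; for edge quadrats, the elevation of the
  quadrat centre minus the mean of its own corners (zero under the
  bilinear surface implied by corner-only data).

Grid orientation: ``corner[r, c]`` sits at easting ``c*side`` and northing
``r*side``; row indices increase northward, column indices eastward.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

HABITATS = ("H1", "H2", "H3")


def quadrat_id(col: int, row: int) -> str:
    return f"Q{col:02d}{row:02d}"


def quadrat_topography(corner_elevations: np.ndarray, quadrat_side: float = 20.0) -> pd.DataFrame:
    """Compute elevation, slope, aspect, convexity per quadrat.

    ``corner_elevations`` has shape (rows+1, cols+1). Returns a DataFrame
    indexed by quadrat id with columns col, row, elevation, slope, aspect,
    convexity. Aspect is NaN for perfectly flat quadrats.
    """
    z = np.asarray(corner_elevations, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2 or z.shape[1] < 2:
        raise ValidationError(f"corner grid must be at least 2x2, got {z.shape}")
    rows, cols = z.shape[0] - 1, z.shape[1] - 1
    s = float(quadrat_side)
    if s <= 0:
        raise ValidationError("quadrat_side must be positive")

    z00 = z[:-1, :-1]  # SW corner of each quadrat
    z01 = z[:-1, 1:]   # SE
    z10 = z[1:, :-1]   # NW
    z11 = z[1:, 1:]    # NE

    elevation = (z00 + z01 + z10 + z11) / 4.0

    def plane_slope(gx, gy):
        return np.degrees(np.arctan(np.hypot(gx, gy)))

    # four 3-corner planes (omit NE, SW, SE, NW respectively)
    slopes = (
        plane_slope((z01 - z00) / s, (z10 - z00) / s)
        + plane_slope((z11 - z10) / s, (z11 - z01) / s)
        + plane_slope((z11 - z10) / s, (z10 - z00) / s)
        + plane_slope((z01 - z00) / s, (z11 - z01) / s)
    ) / 4.0

    # least-squares plane through the 4 corners: gradient components
    gx = ((z01 + z11) - (z00 + z10)) / (2 * s)  # d elevation / d east
    gy = ((z10 + z11) - (z00 + z01)) / (2 * s)  # d elevation / d north
    flat = (np.abs(gx) < 1e-12) & (np.abs(gy) < 1e-12)
    # downslope vector is -(gx, gy); compass angle clockwise from north
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.where(flat, np.nan, aspect)

    convexity = neighbor_convexity(elevation)

    recs = []
    for r in range(rows):
        for c in range(cols):
            recs.append(
                dict(
                    quadrat=quadrat_id(c, r),
                    col=c,
                    row=r,
                    elevation=elevation[r, c],
                    slope=slopes[r, c],
                    aspect=aspect[r, c],
                    convexity=convexity[r, c],
                )
            )
    return pd.DataFrame.from_records(recs).set_index("quadrat")


def neighbor_convexity(elevation: np.ndarray) -> np.ndarray:
    """Quadrat elevation minus the mean elevation of its 8 neighbours.

    Operates on the quadrat-elevation field (rows x cols). Edge quadrats,
    lacking a full neighbourhood, take the centre-minus-own-corner-mean
    convention, which is identically zero on the bilinear surface implied
    by corner-only elevation data.
    """
    elevation = np.asarray(elevation, dtype=float)
    rows, cols = elevation.shape
    convexity = np.zeros_like(elevation)
    if rows >= 3 and cols >= 3:
        nb = np.zeros_like(elevation[1:-1, 1:-1])
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb += elevation[1 + dr : rows - 1 + dr, 1 + dc : cols - 1 + dc]
        convexity[1:-1, 1:-1] = elevation[1:-1, 1:-1] - nb / 8.0
    return convexity


def assign_habitats(frame: pd.DataFrame, habitat_map: pd.Series | dict) -> pd.DataFrame:
    """Attach H1/H2/H3 labels from a quadrat→habitat mapping.

    Every quadrat in ``frame`` must be labelled with a known habitat.
    """
    hm = pd.Series(habitat_map)
    bad = hm[~hm.isin(HABITATS)]
    if len(bad):
        raise ValidationError(f"unknown habitat labels: {dict(bad.head(5))}")
    missing = frame.index.difference(hm.index)
    if len(missing):
        raise ValidationError(f"quadrats without habitat label: {list(missing[:5])}")
    out = frame.copy()
    out["habitat"] = hm.reindex(frame.index)
    return out


def habitats_from_elevation(frame: pd.DataFrame, fractions: tuple[float, float, float]) -> pd.Series:
    """Elevation-tercile habitat generator for synthetic landscapes.

    Lowest-elevation quadrats become H1 (low valley), then H2
    (mid-hillside), highest become H3 (high ridge), with counts matching
    ``fractions`` exactly (largest-remainder rounding). Deterministic:
    ties broken by quadrat id order.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
        raise ValidationError("habitat fractions must be non-negative and sum to 1")
    n = len(frame)
    counts = np.floor(fr * n).astype(int)
    rem = fr * n - counts
    for _ in range(n - counts.sum()):
        i = int(np.argmax(rem))
        counts[i] += 1
        rem[i] = -1
    order = frame["elevation"].sort_values(kind="mergesort").index
    labels = pd.Series(index=frame.index, dtype=object, name="habitat")
    start = 0
    for h, k in zip(HABITATS, counts):
        labels.loc[order[start : start + k]] = h
        start += k
    return labels
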