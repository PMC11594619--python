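"""IUCN criterion-B range metrics and category assignment.

EOO (extent of occurrence) is the spherical area of the convex hull of the
occupied points; AOO (area of occupancy) counts occupied cells of a fixed
2 x 2 km grid. Categories follow the standard criterion-B thresholds
(CR: EOO < 100 or AOO < 10; EN: EOO < 5,000 or AOO < 500; VU: EOO < 20,000
or AOO < 2,000 km²); NT, which IUCN does not define numerically, uses a
configurable margin (default 1.5x a VU threshold) following common
automated-assessment practice. Only the range metrics are evaluated;
subcriteria (fragmentation, continuing decline) are annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_geo import EARTH_RADIUS_KM, Raster

KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0

CATEGORIES = ("LC", "NT", "VU", "EN", "CR")
_RANK = {c: i for i, c in enumerate(CATEGORIES)}

#: criterion-B thresholds, km² (upper bound of each threatened band)
EOO_THRESHOLDS = {"CR": 100.0, "EN": 5_000.0, "VU": 20_000.0}
AOO_THRESHOLDS = {"CR": 10.0, "EN": 500.0, "VU": 2_000.0}


@dataclass
class ThreatResult:
    eoo_km2: float
    aoo_km2: float
    category: str
    criterion: str
    threshold: float | None = None
    extinct: bool = False


def _unit_vectors(lons, lats):
    lam = np.radians(lons)
    phi = np.radians(lats)
    return np.column_stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )


def _spherical_triangle_excess(a, b, c):
    """l'Huilier's formula; a, b, c are side lengths in radians."""
    s = (a + b + c) / 2.0
    t = (
        math.tan(s / 2)
        * math.tan((s - a) / 2)
        * math.tan((s - b) / 2)
        * math.tan((s - c) / 2)
    )
    return 4.0 * math.atan(math.sqrt(max(t, 0.0)))


def spherical_polygon_area_km2(lons, lats) -> float:
    """Area of a convex lon/lat polygon on the R=6371 km sphere.

    Fan triangulation from the first vertex with l'Huilier's excess per
    triangle; vertices must be in boundary order.
    """
    v = _unit_vectors(np.asarray(lons, float), np.asarray(lats, float))

    def angle(p, q):
        return math.atan2(np.linalg.norm(np.cross(p, q)), float(p @ q))

    total = 0.0
    for i in range(1, len(v) - 1):
        a = angle(v[0], v[i])
        b = angle(v[i], v[i + 1])
        c = angle(v[i + 1], v[0])
        if min(a, b, c) < 1e-12:
            continue
        total += _spherical_triangle_excess(a, b, c)
    return total * EARTH_RADIUS_KM**2


def aoo(lons, lats, cell_km: float = 2.0) -> float:
    """Occupied cells of a fixed cell_km grid x cell area (km²).

    The grid is planar, anchored at the (0, 0) graticule after
    equirectangular scaling: x = lon * 111.19 * cos(lat), y = lat * 111.19.
    Origin optimization (allowed by IUCN) is not attempted.
    """
    lons = np.atleast_1d(np.asarray(lons, float))
    lats = np.atleast_1d(np.asarray(lats, float))
    if lons.size == 0:
        raise ValueError("no points")
    x = lons * KM_PER_DEG * np.cos(np.radians(lats))
    y = lats * KM_PER_DEG
    cells = set(zip(np.floor(x / cell_km).astype(int), np.floor(y / cell_km).astype(int)))
    return len(cells) * cell_km**2


def eoo(lons, lats, cell_km: float = 2.0) -> float:
    """Convex-hull extent of occurrence (km², spherical).

    Degenerate inputs (fewer than 3 non-collinear points) fall back to the
    AOO; the result is never smaller than the AOO.
    """
    lons = np.atleast_1d(np.asarray(lons, float))
    lats = np.atleast_1d(np.asarray(lats, float))
    if lons.size == 0:
        raise ValueError("no points")
    aoo_val = aoo(lons, lats, cell_km)
    raw = 0.0
    if lons.size >= 3:
        from scipy.spatial import ConvexHull, QhullError

        try:
            hull = ConvexHull(np.column_stack([lons, lats]))
            vs = hull.vertices
            raw = spherical_polygon_area_km2(lons[vs], lats[vs])
        except QhullError:
            raw = 0.0
    return max(raw, aoo_val)


def _band(value: float, thresholds: dict[str, float], nt_margin: float) -> str:
    if value < thresholds["CR"]:
        return "CR"
    if value < thresholds["EN"]:
        return "EN"
    if value < thresholds["VU"]:
        return "VU"
    if value < thresholds["VU"] * nt_margin:
        return "NT"
    return "LC"


def assign_category(eoo_km2: float, aoo_km2: float, nt_margin: float = 1.5) -> ThreatResult:
    """Criterion-B category from range metrics; the worse of B1/B2 wins."""
    if eoo_km2 < 0 or aoo_km2 < 0:
        raise ValueError("range metrics must be non-negative")
    eoo_km2 = max(eoo_km2, aoo_km2)  # EOO may never undercut AOO
    b1 = _band(eoo_km2, EOO_THRESHOLDS, nt_margin)
    b2 = _band(aoo_km2, AOO_THRESHOLDS, nt_margin)
    if _RANK[b1] > _RANK[b2]:
        cat, crit = b1, "B1"
    elif _RANK[b2] > _RANK[b1]:
        cat, crit = b2, "B2"
    else:
        cat, crit = b1, "B1+B2" if b1 != "LC" else "-"
    return ThreatResult(float(eoo_km2), float(aoo_km2), cat, crit)


def _presence_points(suitability: Raster, threshold: float):
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    present = (suitability.values >= threshold) & ~suitability.nodata_mask
    rows, cols = np.nonzero(present)
    return suitability.spec.cell_center(rows, cols)


def threat_from_raster(suitability: Raster, threshold: float, nt_margin: float = 1.5) -> ThreatResult:
    lon, lat = _presence_points(suitability, threshold)
    if lon.size == 0:
        return ThreatResult(0.0, 0.0, "CR", "B1+B2", threshold=threshold, extinct=True)
    res = assign_category(eoo(lon, lat), aoo(lon, lat), nt_margin)
    res.threshold = threshold
    return res


def threshold_sweep(
    suitability: Raster, thresholds=(0.33, 0.66, 0.90), nt_margin: float = 1.5
) -> list[ThreatResult]:
    """Range metrics and category per presence threshold.

    AOO is necessarily non-increasing in the threshold (asserted); higher
    cut-points can only shrink the predicted range.
    """
    results = [threat_from_raster(suitability, t, nt_margin) for t in sorted(thresholds)]
    for prev, cur in zip(results, results[1:]):
        assert cur.aoo_km2 <= prev.aoo_km2, "AOO must be non-increasing in threshold"
    return results


def scenario_trend(
    current: Raster,
    future: dict[str, dict[str, Raster]],
    threshold: float,
    nt_margin: float = 1.5,
) -> pd.DataFrame:
    """EOO/AOO/category per scenario and period, with cell bookkeeping.

    ``future`` maps scenario label -> period label -> suitability raster.
    Remaining/shrinking counts compare each future presence mask with the
    current one.
    """
    cur_mask = (current.values >= threshold) & ~current.nodata_mask
    rows = []
    for scen, periods in future.items():
        for period, r in periods.items():
            if r.spec != current.spec:
                raise ValueError("future raster grid mismatch")
            res = threat_from_raster(r, threshold, nt_margin)
            fut_mask = (r.values >= threshold) & ~r.nodata_mask
            rows.append(
                {
                    "scenario": scen,
                    "period": period,
                    "threshold": threshold,
                    "eoo_km2": res.eoo_km2,
                    "aoo_km2": res.aoo_km2,
                    "category": res.category,
                    "criterion": res.criterion,
                    "extinct": res.extinct,
                    "remaining_cells": int((cur_mask & fut_mask).sum()),
                    "shrinking_cells": int((cur_mask & ~fut_mask).sum()),
                    "gained_cells": int((~cur_mask & fut_mask).sum()),
                }
            )
    return pd.DataFrame(rows)
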