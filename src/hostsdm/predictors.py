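"""Predictor-set construction: collinearity filtering, the host-richness
biotic layer, and expert-range offset priors selected by AIC.

The offset prior turns an expert range polygon into a normalized
probability surface over grid cells: full weight inside the range and a
logistic decay in normalized distance outside, governed by three
parameters (prob, rate, skew). Candidate offsets over a small parameter
grid are ranked by the AIC of the presence records under each prior
(k = 3 free parameters), and the winner is used either as a
background-sampling bias file or as an additive log-prior.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core_geo import GridSpec, Raster, signed_distance_to_range


def spearman_filter(
    stack: dict[str, Raster],
    contributions: dict[str, float],
    threshold: float = 0.8,
) -> list[str]:
    """Drop the lower-contribution layer of every pair with |rho| > threshold.

    Pairs are processed in descending |rho|; a layer already dropped cannot
    knock out another. The retained names keep the input order. The
    inequality is strict: a pair at exactly rho = threshold is kept.
    """
    names = list(stack)
    for n in names:
        if n not in contributions:
            raise KeyError(f"missing contribution value for layer {n!r}")
    valid = ~np.any([stack[n].nodata_mask for n in names], axis=0)
    data = np.column_stack([stack[n].values[valid] for n in names])
    if len(names) == 1:
        return names
    rho = spearmanr(data).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    pairs = [
        (abs(rho[i, j]), i, j)
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if abs(rho[i, j]) > threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[int] = set()
    for _, i, j in pairs:
        if i in dropped or j in dropped:
            continue
        # tie on contribution: drop the later layer in input order
        loser = j if contributions[names[j]] <= contributions[names[i]] else i
        dropped.add(loser)
    return [n for k, n in enumerate(names) if k not in dropped]


def host_richness(host_suitability: list[Raster], threshold: float = 0.66) -> Raster:
    """Per-cell count of host species predicted present (suitability >= threshold).

    Stacks thresholded host maps; the conventional cut-point 0.66 is the
    IPCC "likely" likelihood class.
    """
    if not host_suitability:
        raise ValueError("need at least one host layer")
    spec = host_suitability[0].spec
    for r in host_suitability[1:]:
        if r.spec != spec:
            raise ValueError("host rasters must share one grid")
    counts = np.zeros(spec.shape, dtype=float)
    mask = np.zeros(spec.shape, dtype=bool)
    for r in host_suitability:
        counts += (r.values >= threshold) & ~r.nodata_mask
        mask |= r.nodata_mask
    return Raster(spec, counts, mask, name="host_richness")


@dataclass(frozen=True)
class OffsetParams:
    """Decay-curve parameters of the expert-range offset prior.

    prob: fraction of total prior mass placed inside the expert range.
    rate: decay steepness on a log10 dial (0 = flat outside; the
          conventional grid is {0, 0.01, 0.1, 10}).
    skew: position of the logistic inflection along the normalized
          outside-distance transect (0, 1).
    """

    prob: float
    rate: float
    skew: float

    def __post_init__(self) -> None:
        if not 0 < self.prob < 1:
            raise ValueError("prob must lie in (0, 1)")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not 0 < self.skew < 1:
            raise ValueError("skew must lie in (0, 1)")


#: number of free parameters of the offset family, used in AIC
OFFSET_K = 3


def rate_steepness(rate: float) -> float:
    """Monotone map from the rate dial to logistic steepness.

    rate_norm = clip((log10(rate) + 3) / 4, 0, inf) sends the conventional
    grid 0.01 / 0.1 / 10 to 0.25 / 0.5 / 1.0; steepness = 4 ln(10) *
    rate_norm, so at rate = 10 the decay spans roughly two decades across
    the normalized transect. rate = 0 gives steepness 0 (flat outside).
    """
    if rate <= 0:
        return 0.0
    rate_norm = max((math.log10(rate) + 3.0) / 4.0, 0.0)
    return 4.0 * math.log(10.0) * rate_norm


@dataclass
class OffsetLayer:
    params: OffsetParams
    raster: Raster  # non-negative, sums to 1 over unmasked cells
    k: int = OFFSET_K
    aic: float | None = None
    log_likelihood: float | None = None


def offset_layer(
    range_polygon,
    spec: GridSpec,
    params: OffsetParams,
    nodata_mask: np.ndarray | None = None,
) -> OffsetLayer:
    """Normalized offset prior for one parameter combination.

    Cells inside the range get unit unnormalized weight. Outside, the
    signed distance is scaled by its 95th percentile (clamped to [0, 1])
    and passed through a falling logistic 1 / (1 + exp(steepness * (x -
    skew))); rate = 0 makes the outside flat. Masses are then rescaled so
    the inside holds exactly ``prob`` of the total, and the layer sums to 1.
    """
    lon, lat = spec.center_grids()
    mask = (
        np.zeros(spec.shape, dtype=bool) if nodata_mask is None else np.asarray(nodata_mask, bool)
    )
    d = signed_distance_to_range(lon.ravel(), lat.ravel(), range_polygon).reshape(
        spec.shape
    )
    inside = (d <= 0) & ~mask
    outside = (d > 0) & ~mask
    if not inside.any():
        raise ValueError("expert range does not overlap the grid")
    if not outside.any():
        raise ValueError("no cells outside the range but prob < 1")
    u = np.zeros(spec.shape)
    u[inside] = 1.0
    d_out = d[outside]
    d95 = np.quantile(d_out, 0.95)
    x = np.clip(d_out / max(d95, 1e-12), 0.0, 1.0)
    s = rate_steepness(params.rate)
    u[outside] = 1.0 / (1.0 + np.exp(s * (x - params.skew)))
    m_in = u[inside].sum()
    m_out = u[outside].sum()
    u[inside] *= params.prob / m_in
    u[outside] *= (1.0 - params.prob) / m_out
    vals = np.where(mask, np.nan, u)
    r = Raster(
        spec,
        vals,
        mask,
        name=f"offset_p{params.prob}_r{params.rate}_s{params.skew}",
    )
    return OffsetLayer(params, r)


def offset_grid(
    range_polygon,
    spec: GridSpec,
    probs=(0.5, 0.7, 0.9),
    rates=(0.0, 0.01, 0.1, 10.0),
    skews=(0.5,),
    nodata_mask: np.ndarray | None = None,
) -> list[OffsetLayer]:
    """Cartesian product of offset parameters (prob outer, skew inner)."""
    return [
        offset_layer(range_polygon, spec, OffsetParams(p, r, s), nodata_mask)
        for p, r, s in itertools.product(probs, rates, skews)
    ]


def select_offset(offsets: list[OffsetLayer], presences: pd.DataFrame) -> OffsetLayer:
    """Lowest-AIC offset under the presence records.

    Each normalized prior is a discrete distribution over cells; the
    log-likelihood of the presences is the sum of log cell values, and
    AIC = 2k - 2 lnL with k = 3. A presence on a zero-mass cell
    disqualifies the candidate (AIC = +inf). Ties break by list order.
    """
    if not offsets:
        raise ValueError("no offset candidates")
    if len(presences) == 0:
        raise ValueError("no presence records")
    lon = presences["lon"].to_numpy(dtype=float)
    lat = presences["lat"].to_numpy(dtype=float)
    best = None
    for off in offsets:
        vals = off.raster.value_at(lon, lat)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            off.aic = math.inf
            off.log_likelihood = -math.inf
            continue
        lnl = float(np.log(vals).sum())
        off.log_likelihood = lnl
        off.aic = 2 * off.k - 2 * lnl
        if best is None or off.aic < best.aic:
            best = off
    if best is None:
        raise ValueError("every offset candidate has a presence on a zero-mass cell")
    return best


def offset_report(offsets: list[OffsetLayer], selected: OffsetLayer) -> pd.DataFrame:
    """Selection table (prob, rate, skew, lnL, AIC, selected flag)."""
    rows = []
    for off in offsets:
        rows.append(
            {
                "prob": off.params.prob,
                "rate": off.params.rate,
                "skew": off.params.skew,
                "log_likelihood": off.log_likelihood,
                "aic": off.aic,
                "selected": off is selected,
            }
        )
    return pd.DataFrame(rows)
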