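"""Virtual landscapes and virtual species with known truth.

The generator emulates the data regime of a host-specialized montane
herbivore study: 19 mutually correlated, spatially autocorrelated
bioclimatic layers plus elevation on a 2.5 arc-min lon/lat grid; six host
plants with distinct unimodal (Gaussian) climate optima; a focal species
whose true occupancy probability depends on climate, elevation, and host
richness; biased presence-only sampling; an expert range polygon derived
from the truth; and "future" layer stacks produced by monotone climate
shifts (additive for temperature, multiplicative for precipitation).

Every generator is reproducible from an integer seed. Layer typing
(temperature vs precipitation) is declared in the config, not inferred.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from shapely.geometry import box
from shapely.ops import unary_union

from .core_geo import GridSpec, Raster, make_occurrence_table

#: bio1..bio11 summarize temperature, bio12..bio19 precipitation (WorldClim
#: convention); elevation is its own type.
TEMPERATURE_LAYERS = tuple(f"bio{i}" for i in range(1, 12))
PRECIPITATION_LAYERS = tuple(f"bio{i}" for i in range(12, 20))


def layer_type(name: str) -> str:
    if name in TEMPERATURE_LAYERS:
        return "temperature"
    if name in PRECIPITATION_LAYERS:
        return "precipitation"
    return "other"


@dataclass
class LandscapeConfig:
    spec: GridSpec = field(
        default_factory=lambda: GridSpec(100.0, 30.0, 2.5 / 60.0, 120, 100)
    )
    n_climate_layers: int = 19
    autocorrelation_length: float = 6.0  # cells
    target_correlation: np.ndarray | None = None
    elevation_relief: float = 2000.0  # meters
    seed: int = 0


def default_correlation(n: int = 19) -> np.ndarray:
    """Correlation among climate layers used by the default scenario.

    Temperature summaries are strongly mutually correlated (annual mean vs
    coldest-quarter mean etc.), precipitation summaries moderately so, and
    the two blocks weakly negatively related — enough structure for the
    |rho| > 0.8 collinearity filter to fire on real pairs.
    """
    c = np.eye(n)
    pairs = {(0, 10): 0.95, (4, 9): 0.9, (11, 15): 0.9, (12, 16): 0.85}
    for (i, j), r in pairs.items():
        if i < n and j < n:
            c[i, j] = c[j, i] = r
    # mild within-block structure
    for i in range(min(11, n)):
        for j in range(i + 1, min(11, n)):
            if c[i, j] == 0:
                c[i, j] = c[j, i] = 0.3
    for i in range(11, n):
        for j in range(i + 1, n):
            if c[i, j] == 0:
                c[i, j] = c[j, i] = 0.25
    # nudge to the nearest PSD matrix if needed
    w, v = np.linalg.eigh(c)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        c = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    return c


def _smooth_field(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    """Unit-variance Gaussian random field with given correlation length."""
    z = rng.standard_normal(shape)
    if length > 0:
        z = gaussian_filter(z, sigma=length, mode="reflect")
        z = (z - z.mean()) / z.std()
    return z


def generate_landscape(cfg: LandscapeConfig) -> dict[str, Raster]:
    """Named stack of climate layers plus elevation.

    Each layer is a smoothed Gaussian field; a Cholesky mix imposes the
    target correlation across layers (smoothing is applied before mixing,
    so the cross-layer correlation is preserved). Temperature layers get a
    latitudinal gradient and a -6.5 K/km elevation lapse; precipitation
    layers are exponentiated to stay positive (so multiplicative future
    shifts are well defined).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_climate_layers
    if n < 1:
        raise ValueError("need at least one climate layer")
    corr = cfg.target_correlation
    if corr is None:
        corr = default_correlation(n)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (n, n) or not np.allclose(corr, corr.T):
        raise ValueError("target_correlation must be a symmetric n x n matrix")
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-8:
        raise ValueError("target_correlation must be positive semi-definite")
    try:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n))
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("target_correlation must be positive semi-definite") from exc

    shape = cfg.spec.shape
    fields = np.stack(
        [_smooth_field(rng, shape, cfg.autocorrelation_length) for _ in range(n)]
    )
    # smoothing shrinks the effective sample size, so whiten the realized
    # covariance before mixing: the stochastic part then carries the target
    # correlation exactly, not just in expectation
    flat = fields.reshape(n, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    cov = flat @ flat.T / flat.shape[1]
    w, v = np.linalg.eigh(cov)
    white = v @ np.diag(1.0 / np.sqrt(np.clip(w, 1e-12, None))) @ v.T @ flat
    mixed = (chol @ white).reshape(n, *shape)

    elev_field = _smooth_field(rng, shape, max(cfg.autocorrelation_length, 1.0))
    elev = (elev_field - elev_field.min()) / (elev_field.max() - elev_field.min() + 1e-12)
    elev = elev * cfg.elevation_relief

    _, lat_grid = cfg.spec.center_grids()
    lat_norm = (lat_grid - lat_grid.mean()) / max(lat_grid.std(), 1e-9)

    stack: dict[str, Raster] = {}
    for i in range(n):
        name = f"bio{i + 1}"
        z = mixed[i]
        if layer_type(name) == "temperature":
            vals = 18.0 + 5.0 * z - 2.0 * lat_norm - 6.5 * (elev / 1000.0)
        else:
            vals = 1200.0 * np.exp(0.4 * z)
        stack[name] = Raster(cfg.spec, vals, np.zeros(shape, dtype=bool), name=name)
    stack["elevation"] = Raster(
        cfg.spec, elev, np.zeros(shape, dtype=bool), name="elevation"
    )
    return stack


@dataclass
class ResponseTerm:
    """One additive term of a species' linear predictor.

    shape 'gaussian': weight * exp(-(x - location)^2 / (2 scale^2))
    shape 'logistic': weight * expit((x - location) / scale)
    """

    layer: str
    shape: str  # gaussian | logistic
    location: float
    scale: float
    weight: float

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            return self.weight * np.exp(-((x - self.location) ** 2) / (2 * self.scale**2))
        if self.shape == "logistic":
            return self.weight * expit((x - self.location) / self.scale)
        raise ValueError(f"unknown response shape {self.shape!r}")


@dataclass
class SpeciesTruth:
    species_id: str
    response_terms: list[ResponseTerm]
    host_dependence_weight: float
    intercept: float
    true_suitability: Raster


def make_truth(
    layers: dict[str, Raster],
    species_id: str,
    response_terms: list[ResponseTerm],
    host_richness: Raster | None = None,
    host_dependence_weight: float = 0.0,
    intercept: float = 0.0,
) -> SpeciesTruth:
    """True occupancy probability = inverse-logit of an additive predictor.

    The host term enters as host_dependence_weight * richness / max(richness),
    encoding the resource-specialization structure (host-rich cells carry
    higher focal probability).
    """
    for term in response_terms:
        if term.layer not in layers:
            raise KeyError(f"unknown layer {term.layer!r}")
    spec = next(iter(layers.values())).spec
    eta = np.full(spec.shape, float(intercept))
    mask = np.zeros(spec.shape, dtype=bool)
    for term in response_terms:
        eta = eta + term.evaluate(layers[term.layer].values)
        mask |= layers[term.layer].nodata_mask
    if host_dependence_weight != 0.0:
        if host_richness is None:
            raise ValueError("host_dependence_weight set but no host_richness given")
        rmax = host_richness.valid_values().max()
        eta = eta + host_dependence_weight * host_richness.values / max(rmax, 1e-12)
        mask |= host_richness.nodata_mask
    truth = Raster(spec, expit(eta), mask, name=f"truth_{species_id}")
    return SpeciesTruth(
        species_id, list(response_terms), host_dependence_weight, intercept, truth
    )


@dataclass
class SamplingConfig:
    n_presences: int = 100
    bias_layer: Raster | None = None
    seed: int = 0


def sample_presences(truth: SpeciesTruth, cfg: SamplingConfig):
    """Presence-only sample: cells drawn without replacement ∝ truth × bias.

    Points land on cell centers, emulating records already snapped to the
    analysis grid. If fewer positive-weight cells exist than requested, all
    of them are returned with a warning.
    """
    if cfg.n_presences < 1:
        raise ValueError("n_presences must be >= 1")
    r = truth.true_suitability
    w = np.where(r.nodata_mask, 0.0, r.values).astype(float)
    if cfg.bias_layer is not None:
        w = w * np.where(cfg.bias_layer.nodata_mask, 0.0, cfg.bias_layer.values)
    w = w.ravel()
    pos = np.flatnonzero(w > 0)
    if pos.size == 0:
        raise ValueError("all sampling weights are zero")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_presences
    if n > pos.size:
        warnings.warn(
            f"requested {n} presences but only {pos.size} positive cells; returning all"
        )
        chosen = pos
    else:
        p = w[pos] / w[pos].sum()
        chosen = rng.choice(pos, size=n, replace=False, p=p)
    rows, cols = np.unravel_index(chosen, r.spec.shape)
    lon, lat = r.spec.cell_center(rows, cols)
    return make_occurrence_table(
        [(truth.species_id, float(x), float(y), "synthetic") for x, y in zip(lon, lat)]
    )


def make_expert_range(
    truth: SpeciesTruth,
    threshold: float = 0.3,
    buffer_km: float = 12.0,
    seed: int = 0,
    vertex_noise_km: float = 0.0,
):
    """Expert range polygon: thresholded truth, dilated, optionally perturbed.

    Mimics a hand-drawn range map: generous edges (buffer) with imprecise
    vertices (seeded jitter). With buffer 0 and no noise the boundary
    follows the cell edges of the thresholded set exactly.
    """
    r = truth.true_suitability
    present = (r.values >= threshold) & ~r.nodata_mask
    if not present.any():
        raise ValueError("no cells reach the expert threshold")
    spec = r.spec
    cs = spec.cell_size
    west, _, _, north = spec.bounds
    boxes = [
        box(west + c * cs, north - (row + 1) * cs, west + (c + 1) * cs, north - row * cs)
        for row, c in zip(*np.nonzero(present))
    ]
    poly = unary_union(boxes)
    deg_per_km = 1.0 / 111.19492664455873
    if buffer_km > 0:
        poly = poly.buffer(buffer_km * deg_per_km, join_style="mitre")
    if vertex_noise_km > 0:
        rng = np.random.default_rng(seed)
        poly = poly.simplify(cs / 2)

        def jitter(geom):
            from shapely.geometry import Polygon as _P

            coords = np.asarray(geom.exterior.coords)
            coords = coords + rng.normal(0, vertex_noise_km * deg_per_km, coords.shape)
            coords[-1] = coords[0]
            return _P(coords)

        from shapely.geometry import MultiPolygon as _MP

        if poly.geom_type == "MultiPolygon":
            poly = _MP([jitter(g) for g in poly.geoms])
        else:
            poly = jitter(poly)
        poly = poly.buffer(0)  # repair any self-intersection from jitter
    return poly


def make_future(
    layers: dict[str, Raster],
    delta_temperature: float | dict[str, float] = 0.0,
    delta_precip_fraction: float | dict[str, float] = 0.0,
) -> dict[str, Raster]:
    """Shifted climate stack: temperature additive, precipitation multiplicative."""
    if isinstance(delta_temperature, dict):
        for k in delta_temperature:
            if k not in layers:
                raise KeyError(f"unknown layer {k!r}")
    if isinstance(delta_precip_fraction, dict):
        for k in delta_precip_fraction:
            if k not in layers:
                raise KeyError(f"unknown layer {k!r}")
    out: dict[str, Raster] = {}
    for name, r in layers.items():
        t = layer_type(name)
        vals = r.values
        if t == "temperature":
            d = (
                delta_temperature.get(name, 0.0)
                if isinstance(delta_temperature, dict)
                else delta_temperature
            )
            vals = vals + d
        elif t == "precipitation":
            f = (
                delta_precip_fraction.get(name, 0.0)
                if isinstance(delta_precip_fraction, dict)
                else delta_precip_fraction
            )
            vals = vals * (1.0 + f)
        out[name] = r.copy_with(vals)
    return out


# ---------------------------------------------------------------------------
# Default study scenario


@dataclass
class Scenario:
    """A complete synthetic study: landscape, hosts, focal species, samples."""

    layers: dict[str, Raster]
    host_truths: list[SpeciesTruth]
    host_richness: Raster
    focal: SpeciesTruth
    focal_presences: object  # occurrence DataFrame
    host_presences: object
    expert_range: object  # shapely polygon
    seed: int


def default_scenario(
    seed: int = 0,
    spec: GridSpec | None = None,
    host_dependence_weight: float = 6.0,
    n_focal_presences: int = 200,
    n_host_presences: int = 170,
    richness_threshold: float = 0.66,
) -> Scenario:
    """The package's reference virtual-species experiment.

    Six host plants with staggered Gaussian optima along the annual-mean
    temperature axis (plus a shared moisture preference) yield a spatially
    fragmented richness surface. The focal herbivore combines a thermal
    optimum, a temperature-seasonality penalty, a mid-elevation optimum, and
    — when ``host_dependence_weight`` > 0 — a strong host-richness term that
    dominates the climate terms. Presence-only samples, the expert range,
    and the landscape all derive from ``seed``.
    """
    from .predictors import host_richness as _host_richness

    cfg = LandscapeConfig(seed=seed)
    if spec is not None:
        cfg.spec = spec
    layers = generate_landscape(cfg)
    bio1 = layers["bio1"].valid_values()
    lo, hi = np.quantile(bio1, [0.15, 0.85])
    optima = np.linspace(lo, hi, 6)
    sd = (hi - lo) / 8.0

    host_truths = []
    host_occ = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    for i, opt in enumerate(optima):
        terms = [
            ResponseTerm("bio1", "gaussian", float(opt), float(sd), 7.0),
            ResponseTerm("bio12", "logistic", 1200.0, 250.0, 2.0),
        ]
        t = make_truth(layers, f"host{i + 1}", terms, intercept=-4.5)
        host_truths.append(t)
        occ = sample_presences(
            t, SamplingConfig(n_host_presences, seed=int(rng.integers(2**31)))
        )
        host_occ.append(occ)
    import pandas as pd

    host_presences = pd.concat(host_occ, ignore_index=True)

    richness = _host_richness(
        [t.true_suitability for t in host_truths], threshold=richness_threshold
    )

    elev_mid = float(np.quantile(layers["elevation"].valid_values(), 0.7))
    focal_terms = [
        ResponseTerm("bio1", "gaussian", float(np.mean(optima)), float(1.5 * sd), 1.5),
        ResponseTerm("elevation", "gaussian", elev_mid, 350.0, 1.5),
    ]
    # baseline keeps landscape prevalence near 15-20% whether or not the
    # host term (which contributes up to +host_dependence_weight) is active
    intercept = -7.0 if host_dependence_weight > 0 else -2.4
    focal = make_truth(
        layers,
        "focal",
        focal_terms,
        host_richness=richness,
        host_dependence_weight=host_dependence_weight,
        intercept=intercept,
    )
    focal_presences = sample_presences(
        focal, SamplingConfig(n_focal_presences, seed=seed + 7)
    )
    expert = make_expert_range(focal, threshold=0.3, buffer_km=12.0, seed=seed)
    return Scenario(
        layers,
        host_truths,
        richness,
        focal,
        focal_presences,
        host_presences,
        expert,
        seed,
    )


def make_path_table(
    n_cells: int,
    betas_richness: dict[str, float],
    betas_focal: dict[str, float],
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Cell table from a known standardized path model, for recovery tests.

    Exogenous standardized predictors (energy, water, elevation) are iid
    normal; richness and focal follow linear models with the given
    standardized coefficients plus Gaussian noise. Returns (DataFrame,
    true standardized coefficient dict) where the truths are rescaled to
    the realized standard deviations of the endogenous variables.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    X = {k: rng.standard_normal(n_cells) for k in ("energy", "water", "elevation")}
    rich = sum(betas_richness[k] * X[k] for k in X) + noise_sd * rng.standard_normal(
        n_cells
    )
    foc = (
        sum(betas_focal[k] * X[k] for k in X)
        + betas_focal["richness"] * rich
        + noise_sd * rng.standard_normal(n_cells)
    )
    df = pd.DataFrame({**X, "richness": rich, "focal": foc})
    s_r, s_f = rich.std(), foc.std()
    true_std = {
        "richness": {k: betas_richness[k] * X[k].std() / s_r for k in X},
        "focal": {
            **{k: betas_focal[k] * X[k].std() / s_f for k in X},
            "richness": betas_focal["richness"] * s_r / s_f,
        },
    }
    return df, true_std
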