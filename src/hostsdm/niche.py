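"""PCA-env climatic-niche comparison between a focal species and its hosts.

Environmental values of every landscape cell are projected onto the first
two principal components of the (standardized) climate space; occurrence
records of each species become kernel-smoothed densities on an R x R grid
over that plane, restricted to the available environment. Overlap is
quantified by Schoener's D and Hellinger-based I, tested against a
grid-shift randomization null, and partitioned into stability / expansion
/ unfilling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core_geo import Raster
from .sdm import extract_env, stack_env


@dataclass
class NicheSpace:
    """First-two-axes PCA of the climate space plus the gridded background.

    ``grid_resolution`` defaults to 100 for desk-scale speed; 1000 (the
    conventional fine setting) is supported.
    """

    loadings: np.ndarray  # (2, p)
    eigenvalues: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    var_names: list[str]
    grid_resolution: int = 100
    extent: tuple[float, float, float, float] | None = None  # x0, x1, y0, y1
    background_density: np.ndarray | None = None
    background_support: np.ndarray | None = None

    def project(self, env: np.ndarray) -> np.ndarray:
        z = (np.asarray(env, dtype=float) - self.means) / self.sds
        return z @ self.loadings.T

    def grid_axes(self):
        x0, x1, y0, y1 = self.extent
        R = self.grid_resolution
        return np.linspace(x0, x1, R + 1), np.linspace(y0, y1, R + 1)


def fit_pca_env(
    env: np.ndarray | dict[str, Raster],
    var_names: list[str] | None = None,
    grid_resolution: int = 100,
) -> NicheSpace:
    """PCA (2 axes) of standardized environmental values of all cells.

    Sign convention: on each axis the largest-magnitude loading is made
    positive, so axes are deterministic across runs.
    """
    if isinstance(env, dict):
        var_names = list(env) if var_names is None else list(var_names)
        X, _, _ = stack_env(env, var_names)
    else:
        X = np.asarray(env, dtype=float)
        if var_names is None:
            var_names = [f"v{i}" for i in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 environmental variables")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    Z = (X - means) / sds
    from sklearn.decomposition import PCA

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.copy()
    for k in range(2):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    space = NicheSpace(
        loadings=loadings,
        eigenvalues=pca.explained_variance_.copy(),
        means=means,
        sds=sds,
        var_names=var_names,
        grid_resolution=grid_resolution,
    )
    pad = 0.05
    x0, x1 = scores[:, 0].min(), scores[:, 0].max()
    y0, y1 = scores[:, 1].min(), scores[:, 1].max()
    dx, dy = pad * (x1 - x0), pad * (y1 - y0)
    space.extent = (x0 - dx, x1 + dx, y0 - dy, y1 + dy)
    bg = _grid_density(space, scores, bandwidth=None, support=None)
    space.background_density = bg
    space.background_support = bg > 0
    return space


def _silverman(x: np.ndarray) -> float:
    n = x.size
    sd = x.std()
    return 1.06 * max(sd, 1e-12) * n ** (-1 / 5)


def _grid_density(space: NicheSpace, scores: np.ndarray, bandwidth, support):
    """Gaussian-smoothed 2-D histogram on the niche grid, normalized to 1."""
    xe, ye = space.grid_axes()
    H, _, _ = np.histogram2d(scores[:, 0], scores[:, 1], bins=[xe, ye])
    cell_x = xe[1] - xe[0]
    cell_y = ye[1] - ye[0]
    bx = _silverman(scores[:, 0]) if bandwidth is None else bandwidth
    by = _silverman(scores[:, 1]) if bandwidth is None else bandwidth
    dens = gaussian_filter(H, sigma=(bx / cell_x, by / cell_y), mode="constant")
    if support is not None:
        dens = dens * support
    total = dens.sum()
    if total <= 0:
        raise ValueError("density has no mass on the available environment")
    return dens / total


def occurrence_density(
    space: NicheSpace,
    occurrences: pd.DataFrame | np.ndarray,
    layers: dict[str, Raster] | None = None,
    bandwidth: float | None = None,
) -> np.ndarray:
    """Normalized kernel density of occurrence scores on the niche grid.

    Accepts either pre-computed scores (n x 2) or an occurrence table plus
    the layer stack. Bandwidth defaults to Silverman's rule per axis; the
    density is multiplied by the available-environment indicator and
    renormalized to sum to 1.
    """
    if isinstance(occurrences, np.ndarray):
        scores = occurrences
    else:
        if layers is None:
            raise ValueError("layers required to project an occurrence table")
        env, _ = extract_env(layers, occurrences, space.var_names)
        scores = space.project(env)
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 occurrences")
    return _grid_density(space, scores, bandwidth, space.background_support)


def _check_normalized(z: np.ndarray, name: str):
    if abs(float(z.sum()) - 1.0) > 1e-6 or (z < 0).any():
        raise ValueError(f"{name} must be a normalized non-negative density")


def schoener_D(z1: np.ndarray, z2: np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 sum|z1 - z2|, in [0, 1]."""
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    _check_normalized(z1, "z1")
    _check_normalized(z2, "z2")
    return float(1.0 - 0.5 * np.abs(z1 - z2).sum())


def hellinger_I(z1: np.ndarray, z2: np.ndarray) -> float:
    """I = 1 - 0.5 sum (sqrt z1 - sqrt z2)^2, in [0, 1]."""
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    _check_normalized(z1, "z1")
    _check_normalized(z2, "z2")
    return float(1.0 - 0.5 * ((np.sqrt(z1) - np.sqrt(z2)) ** 2).sum())


def similarity_test(
    space: NicheSpace,
    z1: np.ndarray,
    z2: np.ndarray,
    reps: int = 100,
    statistic: str = "D",
    seed: int = 0,
) -> dict:
    """Niche-similarity randomization test.

    The null relocates species 2's density by random wrapped grid shifts
    within the background support, recomputing the overlap each time;
    p = (1 + #{null >= observed}) / (reps + 1). The zero shift is excluded.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    stat = {"D": schoener_D, "I": hellinger_I}[statistic]
    observed = stat(z1, z2)
    rng = np.random.default_rng(seed)
    R = space.grid_resolution
    support = space.background_support
    null = np.empty(reps)
    k = 0
    while k < reps:
        di, dj = int(rng.integers(R)), int(rng.integers(R))
        if di == 0 and dj == 0:
            continue
        shifted = np.roll(np.roll(z2, di, axis=0), dj, axis=1)
        shifted = shifted * support
        total = shifted.sum()
        if total <= 0:
            continue
        null[k] = stat(z1, shifted / total)
        k += 1
    p = (1.0 + np.sum(null >= observed)) / (reps + 1.0)
    return {"observed": observed, "null": null, "p": float(p), "statistic": statistic}


@dataclass
class NicheDynamics:
    stability: float
    expansion: float
    unfilling: float


def niche_dynamics(
    z_focal: np.ndarray, z_host: np.ndarray, occupancy_quantile: float = 0.0
) -> NicheDynamics:
    """Stability / expansion / unfilling partition of niche space.

    Occupancy masks keep cells with density above the given quantile of
    nonzero values (quantile 0 = all cells with any density). Expansion and
    stability weight the host density (renormalized over its mask), so
    expansion + stability = 1; unfilling weights the focal density over its
    own mask.
    """
    z_focal = np.asarray(z_focal, float)
    z_host = np.asarray(z_host, float)

    def mask_of(z):
        nz = z[z > 0]
        if nz.size == 0:
            raise ValueError("empty occupancy mask")
        if occupancy_quantile <= 0:
            return z > 0
        return z >= np.quantile(nz, occupancy_quantile)

    m_f = mask_of(z_focal)
    m_h = mask_of(z_host)
    zh = z_host * m_h
    zh = zh / zh.sum()
    zf = z_focal * m_f
    zf = zf / zf.sum()
    stability = float(zh[m_h & m_f].sum())
    expansion = float(zh[m_h & ~m_f].sum())
    unfilling = float(zf[m_f & ~m_h].sum())
    return NicheDynamics(stability=stability, expansion=expansion, unfilling=unfilling)


def niche_analysis(
    layers: dict[str, Raster],
    focal_occurrences: pd.DataFrame,
    host_occurrences: pd.DataFrame,
    var_names: list[str] | None = None,
    grid_resolution: int = 100,
    reps: int = 100,
    seed: int = 0,
) -> dict:
    """End-to-end niche comparison: D, I, similarity p, dynamics."""
    space = fit_pca_env(layers, var_names, grid_resolution)
    z_f = occurrence_density(space, focal_occurrences, layers)
    z_h = occurrence_density(space, host_occurrences, layers)
    sim_D = similarity_test(space, z_f, z_h, reps=reps, statistic="D", seed=seed)
    sim_I = similarity_test(space, z_f, z_h, reps=reps, statistic="I", seed=seed + 1)
    dyn = niche_dynamics(z_f, z_h)
    return {
        "D": sim_D["observed"],
        "p_D": sim_D["p"],
        "I": sim_I["observed"],
        "p_I": sim_I["p"],
        "stability": dyn.stability,
        "expansion": dyn.expansion,
        "unfilling": dyn.unfilling,
        "space": space,
        "z_focal": z_f,
        "z_host": z_h,
    }
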