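"""Presence-background suitability models.

The core is a maximum-entropy model in its penalized-GLM form: the fitted
Gibbs density over background cells, q(x) = exp(beta' f(x)) / Z, maximizes
entropy subject to soft feature-expectation constraints, which is the same
as minimizing

    -mean_presence[beta' f(x)] + log sum_background[exp(beta' f(x))]
        + sum_j lambda_j |beta_j|

over coefficients beta. The optimizer is FISTA (accelerated proximal
gradient with backtracking and restart); the L1 prox gives exact zeros.
Per-feature penalties follow the maxnet convention lambda_j = lambda_mult *
base_class * sd_j / sqrt(n_presence), so with no signal the penalty is on
the order of the sampling noise of the constraint and coefficients stay at
zero.

Output transforms: cloglog (default) 1 - exp(-exp(H) q(x)) with H the
entropy of the background Gibbs distribution, logistic
exp(H) q / (1 + exp(H) q), and raw q itself.

A bagged randomized-trees classifier (random forest) provides the
comparative model behind the same predict contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_geo import GridSpec, Raster, make_occurrence_table

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")

#: base L1 penalty per feature class (lambda_mult scales all of them)
BASE_PENALTY = {
    "linear": 1.0,
    "quadratic": 1.0,
    "product": 1.0,
    "hinge": 0.5,
    "threshold": 1.0,
}


def extract_env(layers: dict[str, Raster], occ: pd.DataFrame, layer_names=None):
    """Per-point environmental matrix (n_points x n_layers)."""
    names = list(layers) if layer_names is None else list(layer_names)
    lon = occ["lon"].to_numpy(dtype=float)
    lat = occ["lat"].to_numpy(dtype=float)
    return np.column_stack([layers[n].value_at(lon, lat) for n in names]), names


def stack_env(layers: dict[str, Raster], layer_names=None):
    """Env matrix over unmasked cells plus the flat cell indices used."""
    names = list(layers) if layer_names is None else list(layer_names)
    mask = np.any([layers[n].nodata_mask for n in names], axis=0)
    idx = np.flatnonzero(~mask.ravel())
    X = np.column_stack([layers[n].values.ravel()[idx] for n in names])
    return X, idx, mask


@dataclass
class FeatureExpansion:
    """Deterministic feature expansion with background min/max normalization."""

    classes: tuple[str, ...] = ("linear", "quadratic", "hinge")
    n_hinge_knots: int = 20
    n_threshold_knots: int = 20
    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None
    var_names: list[str] = field(default_factory=list)

    def fit(self, background_env: np.ndarray, var_names: list[str]) -> "FeatureExpansion":
        for c in self.classes:
            if c not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {c!r}")
        self.mins = np.nanmin(background_env, axis=0)
        self.maxs = np.nanmax(background_env, axis=0)
        self.var_names = list(var_names)
        return self

    def _normalize(self, env: np.ndarray) -> np.ndarray:
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        return np.clip((env - self.mins) / span, 0.0, 1.0)

    def transform(self, env: np.ndarray):
        """Feature matrix plus (name, class, variable) metadata per column."""
        if self.mins is None:
            raise RuntimeError("expansion not fitted")
        z = self._normalize(np.asarray(env, dtype=float))
        cols, meta = [], []
        p = z.shape[1]
        if "linear" in self.classes:
            for j in range(p):
                cols.append(z[:, j])
                meta.append((self.var_names[j], "linear", self.var_names[j]))
        if "quadratic" in self.classes:
            for j in range(p):
                cols.append(z[:, j] ** 2)
                meta.append((f"{self.var_names[j]}^2", "quadratic", self.var_names[j]))
        if "product" in self.classes:
            for i in range(p):
                for j in range(i + 1, p):
                    cols.append(z[:, i] * z[:, j])
                    meta.append(
                        (
                            f"{self.var_names[i]}*{self.var_names[j]}",
                            "product",
                            f"{self.var_names[i]}*{self.var_names[j]}",
                        )
                    )
        if "hinge" in self.classes:
            knots = np.linspace(0.0, 1.0, self.n_hinge_knots + 2)[1:-1]
            for j in range(p):
                for k in knots:
                    cols.append(np.clip((z[:, j] - k) / (1.0 - k), 0.0, 1.0))
                    meta.append((f"h+({self.var_names[j]},{k:.3f})", "hinge", self.var_names[j]))
                    cols.append(np.clip((k - z[:, j]) / k, 0.0, 1.0))
                    meta.append((f"h-({self.var_names[j]},{k:.3f})", "hinge", self.var_names[j]))
        if "threshold" in self.classes:
            knots = np.linspace(0.0, 1.0, self.n_threshold_knots + 2)[1:-1]
            for j in range(p):
                for k in knots:
                    cols.append((z[:, j] > k).astype(float))
                    meta.append((f"t({self.var_names[j]},{k:.3f})", "threshold", self.var_names[j]))
        return np.column_stack(cols), meta


def _fista_l1(F_pres, F_bg, lam, max_iter, tol):
    """Minimize -mean_pres(F b) + logsumexp_bg(F b) + sum lam|b| by FISTA."""
    n_feat = F_pres.shape[1]
    fbar = F_pres.mean(axis=0)

    def smooth_val_grad(b):
        a = F_bg @ b
        m = a.max()
        ea = np.exp(a - m)
        s = ea.sum()
        val = m + math.log(s) - fbar @ b
        p = ea / s
        grad = F_bg.T @ p - fbar
        return val, grad

    def obj(b, val):
        return val + np.abs(b) @ lam

    b = np.zeros(n_feat)
    y = b.copy()
    t = 1.0
    L = 1.0
    val_y, grad_y = smooth_val_grad(y)
    prev_obj = obj(b, smooth_val_grad(b)[0])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # backtracking line search on the smooth part
        while True:
            b_new = np.sign(y - grad_y / L) * np.maximum(
                np.abs(y - grad_y / L) - lam / L, 0.0
            )
            val_new, _ = smooth_val_grad(b_new)
            diff = b_new - y
            quad = val_y + grad_y @ diff + 0.5 * L * diff @ diff
            if val_new <= quad + 1e-12:
                break
            L *= 2.0
        t_new = (1.0 + math.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = b_new + ((t - 1.0) / t_new) * (b_new - b)
        # restart if momentum points uphill
        if (y - b_new) @ (b - b_new) > 0:
            y = b_new.copy()
            t_new = 1.0
        b = b_new
        t = t_new
        val_y, grad_y = smooth_val_grad(y)
        cur_obj = obj(b, val_new)
        if abs(prev_obj - cur_obj) <= tol * max(1.0, abs(cur_obj)):
            converged = True
            break
        prev_obj = cur_obj
        L = max(L / 2.0, 1e-3)
    return b, converged, it


@dataclass
class MaxentModel:
    features: FeatureExpansion
    layer_names: list[str]
    beta: np.ndarray
    feature_meta: list
    lambdas: np.ndarray
    log_z: float  # log sum over training background of exp(beta' f)
    entropy: float  # entropy H of the background Gibbs distribution
    transform: str = "cloglog"
    converged: bool = True
    n_iter: int = 0
    meta: dict = field(default_factory=dict)

    def linear_scores(self, env: np.ndarray) -> np.ndarray:
        F, _ = self.features.transform(env)
        return F @ self.beta

    def predict_env(self, env: np.ndarray, transform: str | None = None) -> np.ndarray:
        """Suitability per row of an environmental matrix."""
        tr = self.transform if transform is None else transform
        # cloglog/logistic saturate well before the exponent overflows
        q = np.exp(np.clip(self.linear_scores(env) - self.log_z, -700.0, 50.0))
        if tr == "raw":
            return q
        eh = math.exp(self.entropy)
        if tr == "cloglog":
            return 1.0 - np.exp(-eh * q)
        if tr == "logistic":
            return eh * q / (1.0 + eh * q)
        raise ValueError(f"unknown transform {tr!r}")

    def predict(self, layers: dict[str, Raster], transform: str | None = None) -> Raster:
        for n in self.layer_names:
            if n not in layers:
                raise KeyError(f"layer {n!r} missing relative to training")
        X, idx, mask = stack_env(layers, self.layer_names)
        spec = layers[self.layer_names[0]].spec
        vals = np.full(spec.shape[0] * spec.shape[1], np.nan)
        vals[idx] = self.predict_env(X, transform)
        return Raster(spec, vals.reshape(spec.shape), mask, name="suitability")

    def background_gibbs_sum(self, background_env: np.ndarray) -> float:
        """Total Gibbs mass over the training background (should be 1)."""
        a = self.linear_scores(background_env)
        return float(np.exp(a - self.log_z).sum())


def penalties(feature_meta, F_all, n_presence, lambda_mult):
    sd = F_all.std(axis=0)
    base = np.array([BASE_PENALTY[m[1]] for m in feature_meta])
    return lambda_mult * base * sd / math.sqrt(max(n_presence, 1))


def fit_maxent(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    layers: dict[str, Raster],
    features: FeatureExpansion | None = None,
    lambda_mult: float = 1.0,
    max_iter: int = 10_000,
    tol: float = 1e-5,
    seed: int = 0,
    transform: str = "cloglog",
    presence_env: np.ndarray | None = None,
    background_env: np.ndarray | None = None,
    layer_names: list[str] | None = None,
) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    ``presence_env``/``background_env`` may be passed to skip re-extraction
    when running many replicates on fixed points. Degenerate features
    (constant over presences and background jointly) are dropped with a
    warning. The fit itself is deterministic; ``seed`` is recorded in the
    model metadata for provenance only.
    """
    if layer_names is None:
        layer_names = list(layers)
    if presence_env is None:
        presence_env, _ = extract_env(layers, presences, layer_names)
    if background_env is None:
        background_env, _ = extract_env(layers, background, layer_names)
    if presence_env.shape[0] < 2:
        raise ValueError("need at least 2 presences")
    feats = features if features is not None else FeatureExpansion()
    if feats.mins is None:
        feats.fit(background_env, layer_names)
    F_pres, meta = feats.transform(presence_env)
    F_bg, _ = feats.transform(background_env)
    F_all = np.vstack([F_pres, F_bg])
    keep = F_all.std(axis=0) > 1e-12
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} degenerate feature(s)")
    if not keep.any():
        raise ValueError("no usable (non-constant) features")
    lam = penalties([m for k, m in zip(keep, meta) if k], F_all[:, keep], len(F_pres), lambda_mult)
    b_kept, converged, n_iter = _fista_l1(
        F_pres[:, keep], F_bg[:, keep], lam, max_iter, tol
    )
    beta = np.zeros(len(meta))
    beta[keep] = b_kept
    lam_full = np.zeros(len(meta))
    lam_full[keep] = lam
    a_bg = F_bg @ beta
    m = a_bg.max()
    log_z = m + math.log(np.exp(a_bg - m).sum())
    p = np.exp(a_bg - log_z)
    entropy = float(-(p * np.log(np.clip(p, 1e-300, None))).sum())
    if not converged:
        warnings.warn("maxent fit hit max_iter before meeting the convergence threshold")
    return MaxentModel(
        features=feats,
        layer_names=list(layer_names),
        beta=beta,
        feature_meta=meta,
        lambdas=lam_full,
        log_z=float(log_z),
        entropy=entropy,
        transform=transform,
        converged=converged,
        n_iter=n_iter,
        meta={
            "seed": seed,
            "n_presence": int(len(F_pres)),
            "n_background": int(len(F_bg)),
            "lambda_mult": lambda_mult,
            "tol": tol,
            "max_iter": max_iter,
        },
    )


def sample_background(
    spec: GridSpec,
    n: int = 10_000,
    weight: Raster | None = None,
    seed: int = 0,
    exclude: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Background cells drawn with replacement, probability ∝ weight.

    Supplying the selected expert-range offset as ``weight`` realizes the
    bias-file mechanism: background effort follows the prior. Cells holding
    ``exclude`` points (normally the presences) are removed from the
    candidate set.
    """
    if weight is None:
        w = np.ones(spec.shape)
    else:
        if weight.spec != spec:
            raise ValueError("weight raster grid mismatch")
        w = np.where(weight.nodata_mask, 0.0, weight.values).astype(float)
    w = w.ravel().copy()
    if exclude is not None and len(exclude):
        r, c = spec.cell_of(exclude["lon"].to_numpy(), exclude["lat"].to_numpy())
        w[np.ravel_multi_index((r, c), spec.shape)] = 0.0
    if not (w > 0).any():
        raise ValueError("all background sampling weights are zero")
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(w.size, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(chosen, spec.shape)
    lon, lat = spec.cell_center(rows, cols)
    return make_occurrence_table(
        [("background", float(x), float(y), "background") for x, y in zip(lon, lat)]
    )


class TreesModel:
    """Bagged randomized-decision-trees presence/background classifier.

    Satisfies the same predict contract as :class:`MaxentModel` (class-1
    probability as suitability)."""

    def __init__(self, clf, layer_names):
        self.clf = clf
        self.layer_names = list(layer_names)

    def predict_env(self, env: np.ndarray, transform=None) -> np.ndarray:
        return self.clf.predict_proba(env)[:, 1]

    def predict(self, layers: dict[str, Raster], transform=None) -> Raster:
        for n in self.layer_names:
            if n not in layers:
                raise KeyError(f"layer {n!r} missing relative to training")
        X, idx, mask = stack_env(layers, self.layer_names)
        spec = layers[self.layer_names[0]].spec
        vals = np.full(spec.shape[0] * spec.shape[1], np.nan)
        vals[idx] = self.predict_env(X)
        return Raster(spec, vals.reshape(spec.shape), mask, name="suitability_trees")


def fit_ensemble_trees(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    layers: dict[str, Raster],
    n_trees: int = 500,
    seed: int = 0,
    presence_env: np.ndarray | None = None,
    background_env: np.ndarray | None = None,
    layer_names: list[str] | None = None,
) -> TreesModel:
    from sklearn.ensemble import RandomForestClassifier

    if layer_names is None:
        layer_names = list(layers)
    if presence_env is None:
        presence_env, _ = extract_env(layers, presences, layer_names)
    if background_env is None:
        background_env, _ = extract_env(layers, background, layer_names)
    if len(presence_env) == 0 or len(background_env) == 0:
        raise ValueError("both presence and background points are required")
    X = np.vstack([presence_env, background_env])
    y = np.concatenate([np.ones(len(presence_env)), np.zeros(len(background_env))])
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, min_samples_leaf=2
    )
    clf.fit(X, y)
    return TreesModel(clf, layer_names)


def split_presences(n: int, train_frac: float, rng: np.random.Generator):
    """Random train/test split; test size = ceil((1 - train_frac) * n)."""
    n_test = math.ceil((1.0 - train_frac) * n)
    perm = rng.permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


@dataclass
class Replicate:
    model: object
    train_idx: np.ndarray
    test_idx: np.ndarray
    panel: dict


@dataclass
class ReplicateSet:
    replicates: list[Replicate]
    model_kind: str
    train_frac: float
    seed: int


def run_replicates(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    layers: dict[str, Raster],
    n: int = 100,
    train_frac: float = 0.75,
    model_kind: str = "maxent",
    seed: int = 0,
    layer_names: list[str] | None = None,
    compute_boyce: bool = True,
    feature_classes: tuple[str, ...] = ("linear", "quadratic", "hinge"),
    lambda_mult: float = 1.0,
    n_trees: int = 500,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ReplicateSet:
    """Bootstrap-style replicated fits with random cross-validation.

    Per replicate a seeded random train/test split of the presences is
    drawn (replicate seeds derive from the master seed); the model is fit
    on the training presences against the full background and the metric
    panel is computed on the held-out presences versus the background.
    Pre-computed ``splits`` allow pairing replicates across predictor
    combinations.
    """
    from .evaluation import metric_panel

    if layer_names is None:
        layer_names = list(layers)
    n_pres = len(presences)
    if n_pres < 4:
        raise ValueError("need at least 4 presences for a 75/25 split")
    pres_env, _ = extract_env(layers, presences, layer_names)
    bg_env, _ = extract_env(layers, background, layer_names)
    if splits is None:
        ss = np.random.SeedSequence(seed)
        splits = [
            split_presences(n_pres, train_frac, np.random.default_rng(s))
            for s in ss.spawn(n)
        ]
    reps = []
    for i, (train_idx, test_idx) in enumerate(splits):
        rep_seed = (seed + 1000003 * (i + 1)) % (2**31)
        if model_kind == "maxent":
            feats = FeatureExpansion(classes=feature_classes)
            model = fit_maxent(
                presences.iloc[train_idx],
                background,
                layers,
                features=feats,
                lambda_mult=lambda_mult,
                seed=rep_seed,
                presence_env=pres_env[train_idx],
                background_env=bg_env,
                layer_names=layer_names,
            )
        elif model_kind == "trees":
            model = fit_ensemble_trees(
                presences.iloc[train_idx],
                background,
                layers,
                n_trees=n_trees,
                seed=rep_seed,
                presence_env=pres_env[train_idx],
                background_env=bg_env,
                layer_names=layer_names,
            )
        else:
            raise ValueError(f"unknown model_kind {model_kind!r}")
        test_scores = model.predict_env(pres_env[test_idx])
        bg_scores = model.predict_env(bg_env)
        suit = model.predict(layers) if compute_boyce else None
        panel = metric_panel(test_scores, bg_scores, suitability=suit)
        reps.append(Replicate(model, train_idx, test_idx, panel))
    return ReplicateSet(reps, model_kind, train_frac, seed)


def panel_frame(repset: ReplicateSet) -> pd.DataFrame:
    return pd.DataFrame([r.panel for r in repset.replicates])


def variable_contribution(
    repset: ReplicateSet,
    presences: pd.DataFrame,
    background: pd.DataFrame,
    layers: dict[str, Raster],
    layer_names: list[str] | None = None,
    n_permutations: int = 10,
    seed: int = 0,
    jackknife: bool = True,
) -> dict:
    """Permutation importance plus jackknife panels.

    Importance of a layer = mean held-out AUC drop when that layer's values
    are permuted across evaluation points (``n_permutations`` seeded
    permutations, averaged over replicates), floored at zero and normalized
    to sum to 100. The jackknife refits the first replicate with each layer
    alone and with each layer left out, reporting test AUC.
    """
    from .evaluation import auc

    if layer_names is None:
        layer_names = repset.replicates[0].model.layer_names
    pres_env, _ = extract_env(layers, presences, layer_names)
    bg_env, _ = extract_env(layers, background, layer_names)
    rng = np.random.default_rng(seed)
    drops = np.zeros(len(layer_names))
    for rep in repset.replicates:
        test_env = pres_env[rep.test_idx]
        base_auc = auc(rep.model.predict_env(test_env), rep.model.predict_env(bg_env))
        for j, name in enumerate(layer_names):
            acc = 0.0
            for _ in range(n_permutations):
                t2 = test_env.copy()
                b2 = bg_env.copy()
                allv = np.concatenate([t2[:, j], b2[:, j]])
                perm = rng.permutation(allv)
                t2[:, j] = perm[: len(t2)]
                b2[:, j] = perm[len(t2):]
                acc += base_auc - auc(rep.model.predict_env(t2), rep.model.predict_env(b2))
            drops[j] += acc / n_permutations
    drops /= max(len(repset.replicates), 1)
    drops = np.maximum(drops, 0.0)
    total = drops.sum()
    if len(layer_names) == 1 or total <= 0:
        contrib = {layer_names[0]: 100.0} if len(layer_names) == 1 else {
            n: 100.0 / len(layer_names) for n in layer_names
        }
    else:
        contrib = {n: 100.0 * d / total for n, d in zip(layer_names, drops)}

    if not jackknife:
        return {"contribution_pct": contrib, "jackknife": None}

    # jackknife on the first replicate's split
    rep0 = repset.replicates[0]
    jack = {}
    train = presences.iloc[rep0.train_idx]
    for name in layer_names:
        only = {name: layers[name]}
        rest_names = [n for n in layer_names if n != name]
        entry = {}
        m_only = _refit(repset, train, background, only, [name])
        te, _ = extract_env(layers, presences.iloc[rep0.test_idx], [name])
        be, _ = extract_env(layers, background, [name])
        entry["alone_auc"] = auc(m_only.predict_env(te), m_only.predict_env(be))
        if rest_names:
            m_rest = _refit(
                repset, train, background, {n: layers[n] for n in rest_names}, rest_names
            )
            te, _ = extract_env(layers, presences.iloc[rep0.test_idx], rest_names)
            be, _ = extract_env(layers, background, rest_names)
            entry["without_auc"] = auc(m_rest.predict_env(te), m_rest.predict_env(be))
        else:
            entry["without_auc"] = float("nan")
        jack[name] = entry
    return {"contribution_pct": contrib, "jackknife": jack}


def _refit(repset, train, background, layers, layer_names):
    if repset.model_kind == "maxent":
        return fit_maxent(
            train,
            background,
            layers,
            features=FeatureExpansion(classes=("linear", "quadratic")),
            layer_names=layer_names,
        )
    return fit_ensemble_trees(train, background, layers, n_trees=200, layer_names=layer_names)


def tune_maxent(
    presences,
    background,
    layers,
    layer_names=None,
    lambda_grid=(0.5, 1.0, 2.0, 4.0),
    feature_sets=(("linear", "quadratic"), ("linear", "quadratic", "hinge")),
    n_replicates: int = 5,
    seed: int = 0,
) -> dict:
    """Small grid search over regularization and feature classes.

    Selects the combination with highest mean held-out AUC — the same idea
    as external SDM-tuning packages, kept deliberately small.
    """
    best = None
    for fc in feature_sets:
        for lm in lambda_grid:
            rs = run_replicates(
                presences,
                background,
                layers,
                n=n_replicates,
                model_kind="maxent",
                seed=seed,
                layer_names=layer_names,
                compute_boyce=False,
                feature_classes=tuple(fc),
                lambda_mult=lm,
            )
            mean_auc = panel_frame(rs)["auc"].mean()
            if best is None or mean_auc > best["mean_auc"]:
                best = {
                    "feature_classes": tuple(fc),
                    "lambda_mult": lm,
                    "mean_auc": float(mean_auc),
                }
    return best
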