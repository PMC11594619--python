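import math

import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from hostsdm.core_geo import GridSpec, Raster, make_occurrence_table
from hostsdm.evaluation import auc
from hostsdm.sdm import (
    FeatureExpansion,
    extract_env,
    fit_ensemble_trees,
    fit_maxent,
    panel_frame,
    run_replicates,
    sample_background,
    split_presences,
    tune_maxent,
    variable_contribution,
)


@pytest.fixture(scope="module")
def world(tiny_scenario):
    """Layers, presences and a shared background on the tiny scenario."""
    sc = tiny_scenario
    spec = sc.focal.true_suitability.spec
    layers = dict(sc.layers)
    layers["host_richness"] = sc.host_richness
    bg = sample_background(spec, n=1000, seed=17, exclude=sc.focal_presences)
    names = ["bio1", "bio4", "bio12", "elevation", "host_richness"]
    return {
        "scenario": sc,
        "spec": spec,
        "layers": {n: layers[n] for n in names},
        "names": names,
        "presences": sc.focal_presences,
        "background": bg,
    }


class TestBackgroundSampling:
    def test_fixed_seed_identical(self, world):
        a = sample_background(world["spec"], n=200, seed=3)
        b = sample_background(world["spec"], n=200, seed=3)
        assert a.equals(b)

    def test_weight_confines_sample(self, world, tiny_scenario):
        from hostsdm.predictors import offset_layer, OffsetParams

        off = offset_layer(
            tiny_scenario.expert_range, world["spec"], OffsetParams(0.999, 10.0, 0.5)
        )
        w = off.raster.copy_with(np.where(off.raster.values > 1e-6, off.raster.values, 0.0))
        bg = sample_background(world["spec"], n=300, weight=w, seed=5)
        vals = w.value_at(bg["lon"].to_numpy(), bg["lat"].to_numpy())
        assert (vals > 0).all()

    def test_uniform_counts_chi_square(self):
        spec = GridSpec(0.0, 5.0, 0.5, 10, 10)
        bg = sample_background(spec, n=10_000, seed=11)
        r, c = spec.cell_of(bg["lon"].to_numpy(), bg["lat"].to_numpy())
        counts = np.bincount(np.ravel_multi_index((r, c), spec.shape), minlength=100)
        assert chisquare(counts).pvalue > 0.01

    def test_all_zero_weight_errors(self, world):
        zero = Raster(world["spec"], np.zeros(world["spec"].shape))
        with pytest.raises(ValueError):
            sample_background(world["spec"], n=10, weight=zero)

    def test_presence_cells_excluded(self, world):
        bg = sample_background(
            world["spec"], n=2000, seed=1, exclude=world["presences"]
        )
        pres_cells = set(
            zip(*world["spec"].cell_of(
                world["presences"]["lon"].to_numpy(),
                world["presences"]["lat"].to_numpy(),
            ))
        )
        bg_cells = set(zip(*world["spec"].cell_of(bg["lon"].to_numpy(), bg["lat"].to_numpy())))
        assert not pres_cells & bg_cells


class TestMaxentFit:
    def test_no_signal_shrinks_to_zero(self, world, rng):
        # presences drawn uniformly from the background cells: L1 penalty
        # should keep essentially all coefficients at zero
        bg = world["background"]
        idx = rng.choice(len(bg), size=100, replace=False)
        pres = bg.iloc[idx].reset_index(drop=True)
        m = fit_maxent(
            pres, bg, world["layers"],
            features=FeatureExpansion(classes=("linear", "quadratic")),
        )
        assert np.max(np.abs(m.beta)) < 0.05
        pred = m.predict(world["layers"])
        assert pred.valid_values().std() < 0.02

    def test_single_binary_feature_concentrates_mass(self):
        # half the background has feature 1 and holds all presences; with a
        # vanishing penalty the Gibbs mass concentrates on those cells
        spec = GridSpec(0.0, 2.0, 1.0, 1, 2)
        n = 50
        bg_env = np.array([[1.0]] * n + [[0.0]] * n)
        pres_env = np.array([[1.0]] * 20)
        dummy = make_occurrence_table([("sp", 0.5, 1.5)] * 20)
        dummy_bg = make_occurrence_table([("bg", 0.5, 1.5)] * (2 * n))
        feats = FeatureExpansion(classes=("linear",))
        m = fit_maxent(
            dummy, dummy_bg, {}, features=feats, lambda_mult=1e-6,
            presence_env=pres_env, background_env=bg_env, layer_names=["f"],
            max_iter=20_000, tol=1e-10,
        )
        q = np.exp(m.linear_scores(bg_env) - m.log_z)
        assert q[:n].sum() > 0.99
        np.testing.assert_allclose(q[:n], q[0], rtol=1e-6)

    def test_parameter_recovery_on_synthetic_truth(self, world):
        sc = world["scenario"]
        m = fit_maxent(
            world["presences"], world["background"], world["layers"],
        )
        pred = m.predict(world["layers"])
        rho = spearmanr(
            pred.values.ravel(), sc.focal.true_suitability.values.ravel()
        ).statistic
        assert rho > 0.9

    def test_gibbs_normalizes(self, world):
        m = fit_maxent(world["presences"], world["background"], world["layers"])
        bg_env, _ = extract_env(world["layers"], world["background"], world["names"])
        assert m.background_gibbs_sum(bg_env) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_feature_dropped_with_warning(self, world):
        layers = dict(world["layers"])
        layers["flat"] = Raster(world["spec"], np.ones(world["spec"].shape))
        with pytest.warns(UserWarning, match="degenerate"):
            m = fit_maxent(
                world["presences"], world["background"], layers,
                features=FeatureExpansion(classes=("linear",)),
            )
        j = [k for k, meta in enumerate(m.feature_meta) if meta[2] == "flat"]
        assert all(m.beta[i] == 0 for i in j)

    def test_too_few_presences_error(self, world):
        one = world["presences"].iloc[:1]
        with pytest.raises(ValueError):
            fit_maxent(one, world["background"], world["layers"])

    def test_l1_path_monotone_nonzeros(self, world):
        nnz = []
        for lm in (0.5, 2.0, 8.0):
            m = fit_maxent(
                world["presences"], world["background"], world["layers"],
                features=FeatureExpansion(classes=("linear", "quadratic")),
                lambda_mult=lm,
            )
            nnz.append(int((m.beta != 0).sum()))
        assert nnz[0] >= nnz[1] >= nnz[2]


class TestPredict:
    def test_zero_coefficients_constant_map(self, world):
        m = fit_maxent(world["presences"], world["background"], world["layers"])
        m.beta = np.zeros_like(m.beta)
        bg_env, _ = extract_env(world["layers"], world["background"], world["names"])
        a = bg_env @ np.zeros(bg_env.shape[1])
        m.log_z = math.log(len(bg_env))
        m.entropy = math.log(len(bg_env))
        pred = m.predict(world["layers"])
        v = pred.valid_values()
        np.testing.assert_allclose(v, v[0])

    def test_monotone_in_linear_predictor(self, world):
        m = fit_maxent(world["presences"], world["background"], world["layers"])
        bg_env, _ = extract_env(world["layers"], world["background"], world["names"])
        scores = m.linear_scores(bg_env)
        suit = m.predict_env(bg_env)
        order = np.argsort(scores)
        assert np.all(np.diff(suit[order]) >= -1e-12)

    def test_cloglog_formula_by_hand(self):
        # two cells, hand-set coefficients: value must match a spreadsheet
        # evaluation of 1 - exp(-e^H * e^a / Z)
        feats = FeatureExpansion(classes=("linear",))
        feats.fit(np.array([[0.0], [1.0]]), ["x"])
        from hostsdm.sdm import MaxentModel

        beta = np.array([1.3])
        a = np.array([0.0, 1.3])  # normalized feature values 0 and 1
        z = np.exp(a).sum()
        p = np.exp(a) / z
        H = float(-(p * np.log(p)).sum())
        m = MaxentModel(
            features=feats, layer_names=["x"], beta=beta,
            feature_meta=[("x", "linear", "x")], lambdas=np.zeros(1),
            log_z=math.log(z), entropy=H,
        )
        got = m.predict_env(np.array([[0.0], [1.0]]))
        expected = 1.0 - np.exp(-math.exp(H) * np.exp(a) / z)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_missing_layer_errors(self, world):
        m = fit_maxent(world["presences"], world["background"], world["layers"])
        partial = {n: world["layers"][n] for n in world["names"][:-1]}
        with pytest.raises(KeyError):
            m.predict(partial)

    def test_train_serve_consistency(self, world):
        # projecting onto the training layers reproduces training-time values
        m = fit_maxent(world["presences"], world["background"], world["layers"])
        pred = m.predict(world["layers"])
        at_presences = pred.value_at(
            world["presences"]["lon"].to_numpy(),
            world["presences"]["lat"].to_numpy(),
        )
        pres_env, _ = extract_env(world["layers"], world["presences"], world["names"])
        np.testing.assert_allclose(at_presences, m.predict_env(pres_env), atol=1e-12)


class TestTrees:
    def test_separable_feature_perfect_auc(self):
        rng = np.random.default_rng(0)
        pres_env = rng.uniform(1.0, 2.0, size=(60, 1))
        bg_env = rng.uniform(-2.0, 0.0, size=(200, 1))
        dummy_p = make_occurrence_table([("sp", 0, 0)] * 60)
        dummy_b = make_occurrence_table([("bg", 0, 0)] * 200)
        m = fit_ensemble_trees(
            dummy_p, dummy_b, {}, n_trees=100,
            presence_env=pres_env, background_env=bg_env, layer_names=["x"],
        )
        test_p = rng.uniform(1.0, 2.0, size=(30, 1))
        test_b = rng.uniform(-2.0, 0.0, size=(100, 1))
        assert auc(m.predict_env(test_p), m.predict_env(test_b)) == 1.0

    def test_shuffled_labels_chance_auc(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 3))
        lab = np.zeros(400, dtype=bool)
        lab[:100] = True
        rng.shuffle(lab)
        dummy_p = make_occurrence_table([("sp", 0, 0)] * 100)
        dummy_b = make_occurrence_table([("bg", 0, 0)] * 300)
        m = fit_ensemble_trees(
            dummy_p, dummy_b, {}, n_trees=200,
            presence_env=X[lab], background_env=X[~lab], layer_names=list("abc"),
        )
        X2 = rng.normal(size=(400, 3))
        lab2 = np.zeros(400, dtype=bool)
        lab2[:100] = True
        rng.shuffle(lab2)
        a = auc(m.predict_env(X2[lab2]), m.predict_env(X2[~lab2]))
        assert abs(a - 0.5) < 0.05

    def test_seed_determinism(self, world):
        m1 = fit_ensemble_trees(
            world["presences"], world["background"], world["layers"], n_trees=50, seed=9
        )
        m2 = fit_ensemble_trees(
            world["presences"], world["background"], world["layers"], n_trees=50, seed=9
        )
        bg_env, _ = extract_env(world["layers"], world["background"], world["names"])
        np.testing.assert_array_equal(m1.predict_env(bg_env), m2.predict_env(bg_env))

    def test_single_class_errors(self, world):
        empty = world["presences"].iloc[:0]
        with pytest.raises(ValueError):
            fit_ensemble_trees(empty, world["background"], world["layers"])


class TestReplicates:
    def test_split_sizes_57_points(self):
        rng = np.random.default_rng(0)
        train, test = split_presences(57, 0.75, rng)
        assert len(test) == 15 and len(train) == 42

    def test_split_disjoint_and_complete(self):
        rng = np.random.default_rng(1)
        train, test = split_presences(101, 0.75, rng)
        assert set(train) & set(test) == set()
        assert len(train) + len(test) == 101

    def test_single_replicate_reproducible(self, world):
        kw = dict(
            n=1, model_kind="maxent", seed=5, compute_boyce=False,
            feature_classes=("linear", "quadratic"),
        )
        a = run_replicates(world["presences"], world["background"], world["layers"], **kw)
        b = run_replicates(world["presences"], world["background"], world["layers"], **kw)
        assert a.replicates[0].panel == b.replicates[0].panel

    def test_too_few_presences_error(self, world):
        three = world["presences"].iloc[:3]
        with pytest.raises(ValueError):
            run_replicates(three, world["background"], world["layers"], n=1)

    def test_every_replicate_disjoint(self, world):
        rs = run_replicates(
            world["presences"], world["background"], world["layers"],
            n=5, compute_boyce=False, feature_classes=("linear",),
        )
        for rep in rs.replicates:
            assert set(rep.train_idx) & set(rep.test_idx) == set()


@pytest.fixture(scope="module")
def contrib(world):
    layers = dict(world["layers"])
    # a pure-noise layer the truth ignores
    rng = np.random.default_rng(123)
    layers["noise"] = Raster(world["spec"], rng.normal(size=world["spec"].shape))
    rs = run_replicates(
        world["presences"], world["background"], layers,
        n=4, compute_boyce=False, feature_classes=("linear", "quadratic"),
        seed=2,
    )
    return variable_contribution(
        rs, world["presences"], world["background"], layers, seed=3,
        n_permutations=5,
    )


class TestVariableContribution:
    def test_sums_to_100(self, contrib):
        assert sum(contrib["contribution_pct"].values()) == pytest.approx(100.0, abs=1e-6)

    def test_noise_layer_negligible(self, contrib):
        assert contrib["contribution_pct"]["noise"] < 5.0

    def test_richness_ranks_first(self, contrib):
        pct = contrib["contribution_pct"]
        assert max(pct, key=pct.get) == "host_richness"

    def test_jackknife_panels_present(self, contrib):
        jk = contrib["jackknife"]
        assert set(jk) == {"bio1", "bio4", "bio12", "elevation", "host_richness", "noise"}
        for entry in jk.values():
            assert 0.0 <= entry["alone_auc"] <= 1.0

    def test_single_layer_gets_100(self, world):
        layers = {"bio1": world["layers"]["bio1"]}
        rs = run_replicates(
            world["presences"], world["background"], layers,
            n=2, compute_boyce=False, feature_classes=("linear",),
        )
        out = variable_contribution(
            rs, world["presences"], world["background"], layers, jackknife=False
        )
        assert out["contribution_pct"] == {"bio1": 100.0}


def test_tune_maxent_returns_valid_combo(world):
    best = tune_maxent(
        world["presences"], world["background"], world["layers"],
        lambda_grid=(1.0, 4.0),
        feature_sets=(("linear", "quadratic"),),
        n_replicates=2,
    )
    assert best["lambda_mult"] in (1.0, 4.0)
    assert 0.5 < best["mean_auc"] <= 1.0
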