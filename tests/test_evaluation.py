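import math

import numpy as np
import pandas as pd
import pytest

from hostsdm.core_geo import GridSpec, Raster
from hostsdm.evaluation import (
    ConfusionTable,
    altitude_profile,
    auc,
    boyce,
    build_cell_table,
    compare_combinations,
    confusion_at,
    max_tss_threshold,
    metric_panel,
    orss,
    path_analysis,
    sedi,
    tss,
    wilcoxon_signed_rank,
)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_all_ties_half(self):
        assert auc([0.5] * 10, [0.5] * 10) == 0.5

    def test_enumerated_pairs(self):
        # pairs: (.9,.5)+ (.9,.1)+ (.4,.5)- (.4,.1)+ -> 3/4
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            auc([], [0.5])

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(loc=-0.5, size=80)
        assert auc(x, y) == pytest.approx(auc(np.exp(x), np.exp(y)))


class TestConfusionMetrics:
    table = ConfusionTable(a=40, b=10, c=10, d=40)

    def test_tss_example(self):
        assert tss(table=self.table) == pytest.approx(0.6)

    def test_tss_perfect(self):
        assert tss(table=ConfusionTable(5, 0, 0, 5)) == 1.0

    def test_tss_constant_scores_zero(self):
        assert tss([0.5] * 5, [0.5] * 5) == pytest.approx(0.0)

    def test_orss_example(self):
        assert orss(self.table) == pytest.approx(1500 / 1700, abs=1e-5)

    def test_orss_perfect(self):
        assert orss(ConfusionTable(5, 0, 0, 5)) == 1.0

    def test_orss_no_skill(self):
        assert orss(ConfusionTable(10, 10, 10, 10)) == 0.0

    def test_orss_undefined_flagged_nan(self):
        # ad = bc = 0: the score is undefined
        assert math.isnan(orss(ConfusionTable(0, 5, 0, 3)))

    def test_sedi_example(self):
        # H=0.8, F=0.2
        assert sedi(self.table) == pytest.approx(0.7565, abs=1e-3)

    def test_sedi_zero_when_h_equals_f(self):
        assert sedi(ConfusionTable(20, 20, 80, 80)) == pytest.approx(0.0, abs=1e-12)

    def test_sedi_extremal_limit(self):
        v = sedi(ConfusionTable(10**6, 0, 0, 10**6))
        assert 0.99 < v <= 1.0

    def test_perfect_table_all_ones(self):
        t = ConfusionTable(7, 0, 0, 13)
        assert tss(table=t) == 1.0
        assert orss(t) == 1.0
        assert sedi(t) > 0.99

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(-1, 0, 0, 2)

    def test_max_tss_threshold_recovers_separator(self):
        t, v = max_tss_threshold([0.8, 0.9, 0.7], [0.1, 0.2, 0.3])
        assert v == 1.0
        assert 0.3 < t <= 0.7


@pytest.fixture(scope="module")
def suit_map():
    spec = GridSpec(0.0, 10.0, 0.1, 100, 100)
    rng = np.random.default_rng(5)
    return Raster(spec, rng.uniform(size=spec.shape))


class TestBoyce:

    def test_calibrated_sampling_high_boyce(self, suit_map):
        rng = np.random.default_rng(6)
        flat = suit_map.values.ravel()
        idx = rng.choice(flat.size, size=2000, replace=True, p=flat / flat.sum())
        assert boyce(flat[idx], suit_map) > 0.9

    def test_anticalibrated_sampling_negative_boyce(self, suit_map):
        rng = np.random.default_rng(7)
        flat = suit_map.values.ravel()
        w = 1.0 - flat
        idx = rng.choice(flat.size, size=2000, replace=True, p=w / w.sum())
        assert boyce(flat[idx], suit_map) < -0.9

    def test_constant_map_flagged_nan(self):
        spec = GridSpec(0.0, 1.0, 0.1, 10, 10)
        const = Raster(spec, np.full(spec.shape, 0.4))
        assert math.isnan(boyce([0.4, 0.4], const))

    def test_monotone_transform_invariance(self, suit_map):
        rng = np.random.default_rng(8)
        flat = suit_map.values.ravel()
        idx = rng.choice(flat.size, size=1000, replace=True, p=flat / flat.sum())
        b1 = boyce(flat[idx], suit_map)
        # common monotone rescale of map and presence scores
        squared = suit_map.copy_with(suit_map.values**2)
        b2 = boyce(flat[idx] ** 2, squared)
        assert b1 == pytest.approx(b2, abs=0.1)
        assert (b1 > 0.5) == (b2 > 0.5)


class TestWilcoxon:
    def test_identical_samples_p1(self):
        assert wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_exact_n5_all_positive(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [0.5, 1.2, 2.1, 3.3, 4.0]
        assert wilcoxon_signed_rank(x, y) == pytest.approx(2 / 32)

    def test_exact_n6_all_positive(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [0.5, 1.2, 2.1, 3.3, 4.0, 5.2]
        assert wilcoxon_signed_rank(x, y) == pytest.approx(2 / 64)

    def test_large_sample_normal_approx(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60) + 1.0
        p = wilcoxon_signed_rank(x, y)
        assert p < 1e-6


class TestCompareCombinations:
    def test_identical_combinations_all_p1(self, tiny_scenario):
        from hostsdm.sdm import sample_background

        sc = tiny_scenario
        spec = sc.focal.true_suitability.spec
        bg = sample_background(spec, n=400, seed=3, exclude=sc.focal_presences)
        names = ["bio1", "elevation"]
        stack = {n: sc.layers[n] for n in names}
        res = compare_combinations(
            sc.focal_presences,
            {"A": stack, "B": stack},
            bg,
            n_replicates=4,
            seed=1,
            compute_boyce=False,
            feature_classes=("linear",),
        )
        computed = res.pvalues.query("metric != 'boyce'")
        assert (computed["p"] == 1.0).all()

    def test_host_layer_improves_auc(self, tiny_scenario):
        from hostsdm.sdm import sample_background

        sc = tiny_scenario
        spec = sc.focal.true_suitability.spec
        bg = sample_background(spec, n=500, seed=3, exclude=sc.focal_presences)
        base = {n: sc.layers[n] for n in ("bio1", "bio4", "bio12", "elevation")}
        with_h = dict(base)
        with_h["host_richness"] = sc.host_richness
        res = compare_combinations(
            sc.focal_presences,
            {"C": base, "C+H": with_h},
            bg,
            n_replicates=12,
            seed=2,
            compute_boyce=False,
            feature_classes=("linear", "quadratic"),
        )
        row = res.pvalues.query("metric == 'auc'").iloc[0]
        assert row["mean_b"] > row["mean_a"]
        assert row["p"] < 0.05


class TestPathAnalysis:
    def test_noiseless_chain(self):
        # focal = richness = elevation exactly
        rng = np.random.default_rng(0)
        elev = rng.standard_normal(2000)
        df = pd.DataFrame(
            {
                "energy": rng.standard_normal(2000),
                "water": rng.standard_normal(2000),
                "elevation": elev,
                "richness": elev,
                "focal": elev,
            }
        )
        out = path_analysis(df)
        assert out["richness_model"]["elevation"]["coef"] == pytest.approx(1.0, abs=1e-6)
        assert out["effects"]["richness"]["direct"] + out["effects"]["elevation"][
            "direct"
        ] == pytest.approx(1.0, abs=1e-6)
        assert out["effects"]["elevation"]["total"] == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_predictor_near_zero(self):
        rng = np.random.default_rng(1)
        n = 5000
        energy = rng.standard_normal(n)
        water = rng.standard_normal(n)  # irrelevant
        elev = rng.standard_normal(n)
        rich = 0.8 * energy + 0.1 * rng.standard_normal(n)
        focal = 0.7 * rich + 0.2 * elev + 0.1 * rng.standard_normal(n)
        df = pd.DataFrame(
            {"energy": energy, "water": water, "elevation": elev,
             "richness": rich, "focal": focal}
        )
        out = path_analysis(df)
        assert abs(out["focal_model"]["water"]["coef"]) < 0.05
        assert abs(out["richness_model"]["water"]["coef"]) < 0.05

    def test_recovers_generative_betas(self):
        from hostsdm.synthetic_data import make_path_table

        df, truth = make_path_table(
            5000,
            betas_richness={"energy": 0.5, "water": 0.3, "elevation": -0.4},
            betas_focal={"energy": 0.2, "water": 0.1, "elevation": 0.3, "richness": 0.6},
            noise_sd=0.1,
            seed=4,
        )
        out = path_analysis(df)
        for var, b in truth["richness"].items():
            assert out["richness_model"][var]["coef"] == pytest.approx(b, abs=0.05)
        for var, b in truth["focal"].items():
            assert out["focal_model"][var]["coef"] == pytest.approx(b, abs=0.05)

    def test_collinear_design_errors(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        df = pd.DataFrame(
            {"energy": x, "water": x, "elevation": x, "richness": x, "focal": x}
        )
        with pytest.raises(ValueError, match="condition number"):
            path_analysis(df)

    def test_build_cell_table_columns(self, tiny_scenario):
        sc = tiny_scenario
        table = build_cell_table(
            sc.layers, sc.host_richness, sc.focal.true_suitability
        )
        assert list(table.columns) == ["energy", "water", "elevation", "richness", "focal"]
        assert len(table) == np.prod(sc.host_richness.spec.shape)


class TestAltitudeProfile:
    spec = GridSpec(0.0, 10.0, 0.1, 40, 40)

    def _elev(self, shift=0.0):
        rows = np.linspace(200, 1800, self.spec.n_rows)[:, None]
        return Raster(self.spec, np.broadcast_to(rows, self.spec.shape) + shift)

    def test_support_matches_band(self):
        elev = self._elev()
        suit = Raster(
            self.spec,
            np.where((elev.values >= 500) & (elev.values <= 1500), 1.0, 0.0),
        )
        prof = altitude_profile(suit, elev, presence_threshold=0.5)
        nz = prof[prof["count"] > 0]
        assert nz["bin_left"].min() >= 400
        assert nz["bin_right"].max() <= 1600

    def test_empty_profile_flagged(self):
        elev = self._elev()
        suit = Raster(self.spec, np.zeros(self.spec.shape))
        prof = altitude_profile(suit, elev, presence_threshold=0.5)
        assert prof["empty"].all()
        assert prof["count"].sum() == 0

    def test_shift_translates_profile(self):
        elev = self._elev()
        suit = Raster(
            self.spec,
            np.where((elev.values >= 500) & (elev.values < 1500), 1.0, 0.0),
        )
        p0 = altitude_profile(suit, elev, 0.5)
        p1 = altitude_profile(suit, self._elev(shift=100.0), 0.5)
        c0 = p0.set_index("bin_left")["count"]
        c1 = p1.set_index("bin_left")["count"]
        common = [b for b in c0.index if b + 100 in c1.index]
        assert all(c1[b + 100] == c0[b] for b in common)

    def test_grid_mismatch_errors(self):
        other = GridSpec(0.0, 10.0, 0.2, 20, 20)
        with pytest.raises(ValueError):
            altitude_profile(
                Raster(other, np.zeros(other.shape)), self._elev(), 0.5
            )


def test_metric_panel_flags_nan_metrics():
    spec = GridSpec(0.0, 1.0, 0.1, 10, 10)
    const = Raster(spec, np.full(spec.shape, 0.5))
    panel = metric_panel([0.5, 0.5], [0.5, 0.5, 0.5], suitability=const)
    assert "boyce" in panel["flags"]
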