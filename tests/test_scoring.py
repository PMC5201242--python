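import numpy as np
import pytest
from sklearn.base import clone

from prs2d.scoring import (
    PRSScorer,
    ThresholdGridSearch,
    binary_metrics,
    build_prs_model,
    optimize_thresholds,
    prediction_r2,
    read_model,
    score_samples,
    write_model,
)
from prs2d.sumstats import SnpPartition

from conftest import make_panel, make_summary


@pytest.fixture
def three_snp_summary():
    return make_summary(
        ["rs0", "rs1", "rs2"],
        [0.30, 0.10, -0.05],
        [0.05, 0.05, 0.05],
    )


class TestBuildModel:
    def test_alpha_one_no_correction_keeps_all_raw_betas(self, three_snp_summary):
        model = build_prs_model(three_snp_summary, ["rs0", "rs1", "rs2"], None, 1.0)
        assert len(model) == 3
        np.testing.assert_allclose(
            model.entries.set_index("snp_id")["weight"][["rs0", "rs1", "rs2"]],
            [0.30, 0.10, -0.05],
        )

    def test_strict_selection_by_p(self):
        summary = make_summary(["a", "b"], [0.1, 0.1], [0.1, 0.1], ps=[0.001, 0.2])
        model = build_prs_model(summary, ["a", "b"], None, 0.01)
        assert list(model.entries["snp_id"]) == ["a"]

    def test_two_d_group_specific_thresholds(self):
        """A SNP with P = 0.02 enters at (0.03, 0.005) only through the HP set."""
        summary = make_summary(["hp1", "lp1"], [0.1, 0.1], [0.1, 0.1], ps=[0.02, 0.02])
        part = SnpPartition(frozenset({"hp1", "lp1"}), frozenset({"hp1"}))
        model = build_prs_model(summary, ["hp1", "lp1"], part, 0.03, 0.005)
        assert list(model.entries["snp_id"]) == ["hp1"]
        assert model.entries["group"].iloc[0] == "HP"

    def test_partition_must_cover_clumped(self, three_snp_summary):
        part = SnpPartition(frozenset({"rs0"}), frozenset({"rs0"}))
        with pytest.raises(ValueError, match="cover"):
            build_prs_model(three_snp_summary, ["rs0", "rs1"], part, 0.5, 0.5)

    def test_two_d_requires_alpha2(self, three_snp_summary):
        part = SnpPartition(frozenset({"rs0", "rs1", "rs2"}), frozenset({"rs0"}))
        with pytest.raises(ValueError, match="alpha2"):
            build_prs_model(three_snp_summary, ["rs0", "rs1", "rs2"], part, 0.5)

    def test_lasso_weights_are_soft_thresholded(self, three_snp_summary):
        from prs2d.shrinkage import lasso_correct

        model = build_prs_model(three_snp_summary, ["rs0", "rs1", "rs2"], None, 0.05, method="lasso")
        w = model.entries.set_index("snp_id")["weight"]
        assert w["rs0"] == pytest.approx(lasso_correct(0.30, 0.05, 0.05))

    def test_roundtrip_serialization(self, three_snp_summary, tmp_path):
        model = build_prs_model(three_snp_summary, ["rs0", "rs1"], None, 1.0, method="lasso")
        path = tmp_path / "model.tsv"
        write_model(model, path)
        back = read_model(path)
        assert back.alpha1 == model.alpha1 and back.method == "lasso"
        np.testing.assert_allclose(back.entries["weight"], model.entries["weight"])


class TestScoreSamples:
    def test_empty_model_scores_zero(self, three_snp_summary, rng):
        model = build_prs_model(three_snp_summary, ["rs2"], None, 1e-12)
        panel = make_panel(rng.binomial(2, 0.3, (10, 3)).astype(float))
        sv = score_samples(model, panel)
        np.testing.assert_array_equal(sv.scores, 0.0)

    def test_hand_computed_dot_product(self):
        summary = make_summary(["rs0", "rs1", "rs2"], [0.2, -0.1, 0.05], [0.02, 0.02, 0.02])
        model = build_prs_model(summary, ["rs0", "rs1", "rs2"], None, 1.0)
        dosages = np.array([[0, 1, 2], [1, 1, 0], [2, 1, 1], [1, 1, 1]], dtype=float)
        panel = make_panel(dosages)
        g = (dosages - dosages.mean(0)) / np.where(dosages.std(0) > 0, dosages.std(0), 1)
        expected = g @ np.array([0.2, -0.1, 0.05])
        sv = score_samples(model, panel)
        np.testing.assert_allclose(sv.scores, expected, atol=1e-12)

    def test_allele_swap_flips_weight(self, rng):
        summary = make_summary(["rs0"], [0.2], [0.02], effect=["G"], other=["A"])
        model = build_prs_model(summary, ["rs0"], None, 1.0)
        dos = rng.binomial(2, 0.4, (50, 1)).astype(float)
        panel = make_panel(dos, counted=["A"], other=["G"])  # counted allele is A
        sv = score_samples(model, panel)
        g = (dos[:, 0] - dos[:, 0].mean()) / dos[:, 0].std()
        np.testing.assert_allclose(sv.scores, -0.2 * g, atol=1e-12)

    def test_no_overlap_is_error(self, three_snp_summary, rng):
        model = build_prs_model(three_snp_summary, ["rs0"], None, 1.0)
        panel = make_panel(rng.binomial(2, 0.3, (10, 1)).astype(float))
        panel.snp_map.loc[0, "snp_id"] = "other"
        panel._index = panel.snp_map["snp_id"].pipe(lambda s: s.to_frame().set_index("snp_id").index)
        with pytest.raises(ValueError):
            score_samples(model, panel)


class TestMetrics:
    def test_r2_perfect_and_degenerate(self, rng):
        x = rng.normal(size=100)
        assert prediction_r2(x, x) == pytest.approx(1.0)
        assert prediction_r2(np.ones(100), x) == 0.0

    def test_r2_null_small(self, rng):
        a, b = rng.normal(size=10_000), rng.normal(size=10_000)
        assert prediction_r2(a, b) < 0.002

    def test_auc_enumerated_example(self):
        # cases {2,3}, controls {1,2}: pairs (2>1)+(2=2)/2+(3>1)+(3>2) = 3.5/4
        scores = np.array([2.0, 3.0, 1.0, 2.0])
        y = np.array([1, 1, 0, 0])
        auc, nag = binary_metrics(scores, y)
        assert auc == pytest.approx(0.875)
        assert 0 <= nag <= 1

    def test_auc_null_and_degenerate(self, rng):
        y = rng.integers(0, 2, 20_000)
        s = rng.normal(size=20_000)
        auc, _ = binary_metrics(s, y)
        assert auc == pytest.approx(0.5, abs=0.02)
        auc0, nag0 = binary_metrics(np.ones(100), np.r_[np.ones(50), np.zeros(50)])
        assert (auc0, nag0) == (0.5, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics(np.arange(5.0), np.ones(5))


class TestOptimizeThresholds:
    def test_single_point_grid(self, small_scenario):
        panel, _, _, _, y, summary = small_scenario
        ids = list(summary.snp_ids)[:50]
        (a1, a2), best, surface = optimize_thresholds(summary, ids, None, panel, y, [1.0])
        assert (a1, a2) == (1.0, None)
        assert len(surface) == 1

    def test_2d_equal_thresholds_reproduce_1d(self, small_scenario):
        panel, _, partition, _, y, summary = small_scenario
        ids = list(summary.snp_ids)[:200]
        part = SnpPartition.from_hp(ids, partition.hp)
        grid = [1e-3, 0.05, 1.0]
        _, _, s1 = optimize_thresholds(summary, ids, None, panel, y, grid)
        _, _, s2 = optimize_thresholds(summary, ids, part, panel, y, grid)
        for a in grid:
            r1 = s1.loc[s1["alpha1"] == a, "r2"].iloc[0]
            r2 = s2.loc[(s2["alpha1"] == a) & (s2["alpha2"] == a), "r2"].iloc[0]
            assert r1 == pytest.approx(r2, abs=1e-12)

    def test_lasso_at_alpha_one_equals_none(self, small_scenario):
        panel, _, _, _, y, summary = small_scenario
        ids = list(summary.snp_ids)[:100]
        _, _, s_none = optimize_thresholds(summary, ids, None, panel, y, [1.0], "none")
        _, _, s_lasso = optimize_thresholds(summary, ids, None, panel, y, [1.0], "lasso")
        assert s_none["r2"].iloc[0] == s_lasso["r2"].iloc[0]

    def test_surface_reproducible_bit_identically(self, small_scenario):
        panel, _, _, _, y, summary = small_scenario
        ids = list(summary.snp_ids)[:100]
        grid = [1e-3, 0.05, 1.0]
        _, _, s1 = optimize_thresholds(summary, ids, None, panel, y, grid)
        _, _, s2 = optimize_thresholds(summary, ids, None, panel, y, grid)
        assert s1.equals(s2)

    def test_bad_grid_rejected(self, small_scenario):
        panel, _, _, _, y, summary = small_scenario
        with pytest.raises(ValueError):
            optimize_thresholds(summary, list(summary.snp_ids)[:5], None, panel, y, [])


class TestSklearnSurface:
    def test_scorer_fit_transform_matches_score_samples(self, small_scenario):
        panel, _, _, _, y, summary = small_scenario
        ids = list(summary.snp_ids)[:100]
        est = PRSScorer(summary, ids, alpha1=0.05, method="lasso").fit(panel)
        model = build_prs_model(summary, ids, None, 0.05, method="lasso")
        sv = score_samples(model, panel)
        np.testing.assert_allclose(est.transform(panel), sv.scores, atol=1e-10)
        assert est.score(panel, y) == pytest.approx(prediction_r2(sv, y), abs=1e-12)

    def test_estimators_are_cloneable(self, three_snp_summary):
        est = PRSScorer(three_snp_summary, alpha1=0.1, method="mle")
        params = est.get_params()
        assert params["alpha1"] == 0.1 and params["method"] == "mle"
        clone(est)  # sklearn clone contract
        clone(ThresholdGridSearch(three_snp_summary, grid=[0.1, 1.0]))

    def test_grid_search_finds_surface_argmax(self, small_scenario):
        panel, _, partition, _, y, summary = small_scenario
        ids = list(summary.snp_ids)[:200]
        gs = ThresholdGridSearch(
            summary, ids, hp_ids=partition.hp, grid=[1e-3, 0.05, 1.0], method="lasso"
        ).fit(panel, y)
        best_row = gs.surface_.loc[gs.surface_["r2"].idxmax()]
        assert gs.best_score_ == best_row["r2"]
        assert gs.best_alpha1_ == best_row["alpha1"]
        # refitted scorer reproduces the tuned score on the same panel
        assert gs.score(panel, y) == pytest.approx(gs.best_score_, abs=1e-10)
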