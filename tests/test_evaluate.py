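import numpy as np
import pytest
from scipy import special, stats

from prs2d.evaluate import (
    FoldResult,
    bootstrap_improvement_test,
    calibration_slope,
    enrichment_fold,
    enrichment_qq,
    kfold_prediction,
    paired_improvement_test,
    parse_method,
    risk_stratification,
)
from prs2d.simulate import SimConfig, assign_causal_and_hp, draw_effect_sizes, simulate_genotype_panel, simulate_trait
from prs2d.sumstats import SnpPartition

from conftest import make_summary


class TestParseMethod:
    def test_labels(self):
        assert parse_method("2d-lasso") == (True, "lasso")
        assert parse_method("1D-MLE") == (False, "mle")
        with pytest.raises(ValueError):
            parse_method("3d-ridge")


class TestPairedImprovementTest:
    def test_worked_value(self):
        """deltas [0.01, 0.02, 0.015, 0.005, 0.02]: T = 4.802, p ~ 0.0043."""
        deltas = [0.01, 0.02, 0.015, 0.005, 0.02]
        res = paired_improvement_test(deltas)
        mean = np.mean(deltas)
        s = np.std(deltas, ddof=1)
        assert mean == pytest.approx(0.014)
        assert s == pytest.approx(0.006519, abs=1e-6)
        assert res.statistic == pytest.approx(4.802, abs=1e-3)
        # independent t CDF route (incomplete beta, not scipy.stats.t)
        df = 4
        x = df / (df + res.statistic**2)
        p_indep = 0.5 * special.betainc(df / 2, 0.5, x)
        assert res.pvalue == pytest.approx(p_indep, abs=1e-10)
        assert res.pvalue == pytest.approx(0.0043, abs=3e-4)

    def test_sign_antisymmetry(self):
        deltas = [0.01, -0.004, 0.02, 0.003]
        plus = paired_improvement_test(deltas)
        minus = paired_improvement_test([-d for d in deltas])
        assert minus.statistic == pytest.approx(-plus.statistic)
        assert minus.pvalue == pytest.approx(1 - plus.pvalue)

    def test_degenerate_constant_deltas(self):
        assert paired_improvement_test([0.0, 0.0, 0.0]) == (0.0, 0.5, True)
        assert paired_improvement_test([0.01, 0.01]).pvalue == 0.0
        assert paired_improvement_test([-0.01, -0.01]).pvalue == 1.0

    def test_accepts_fold_results_and_ignores_order(self):
        folds = [FoldResult(i, 0.1, 0.1 + d) for i, d in enumerate([0.01, 0.02, 0.005])]
        a = paired_improvement_test(folds)
        b = paired_improvement_test(folds[::-1])
        assert a == b


class TestBootstrap:
    def test_identical_scores_give_half(self, rng):
        y = rng.normal(size=300)
        s = rng.normal(size=300)
        delta, p = bootstrap_improvement_test(s, s, y, b=200, seed=1)
        assert delta == 0.0
        assert p == pytest.approx(0.5, abs=0.1)

    def test_deterministic_given_seed(self, rng):
        y = rng.normal(size=200)
        s0, s1 = rng.normal(size=200), rng.normal(size=200)
        assert bootstrap_improvement_test(s0, s1, y, b=150, seed=3) == (
            bootstrap_improvement_test(s0, s1, y, b=150, seed=3)
        )

    def test_detects_real_improvement(self, rng):
        n = 3_000
        signal = rng.normal(size=n)
        y = signal + rng.normal(0, 2.0, n)
        s_base = 0.05 * signal + rng.normal(0, 1, n)  # weak predictor
        s_alt = signal + 0.3 * rng.normal(0, 1, n)  # strong predictor
        hits = sum(
            bootstrap_improvement_test(s_base, s_alt, y, b=300, seed=k)[1] < 0.05
            for k in range(10)
        )
        assert hits >= 9

    def test_too_few_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_improvement_test(np.arange(9.0), np.arange(9.0), np.arange(9.0), b=10)


class TestEnrichmentFold:
    def test_paper_scale_arithmetic(self):
        universe = frozenset(f"s{i}" for i in range(53_163))
        hp = frozenset(f"s{i}" for i in range(9_940))
        causal = frozenset(f"s{i}" for i in range(2_805)) | frozenset(
            f"s{i}" for i in range(20_000, 22_195)
        )
        part = SnpPartition(universe, hp)
        assert len(causal) == 5_000 and len(hp & causal) == 2_805
        assert enrichment_fold(part, causal) == pytest.approx(3.0006, abs=1e-3)

    def test_random_hp_has_expectation_one(self, rng):
        universe = [f"s{i}" for i in range(1_000)]
        causal = frozenset(rng.choice(universe, 100, replace=False))
        folds = []
        for _ in range(200):
            hp = frozenset(rng.choice(universe, 200, replace=False))
            folds.append(enrichment_fold(SnpPartition(frozenset(universe), hp), causal))
        se = np.std(folds, ddof=1) / np.sqrt(len(folds))
        assert abs(np.mean(folds) - 1.0) < 3 * se + 1e-9

    def test_maximal_enrichment(self):
        universe = frozenset(f"s{i}" for i in range(100))
        causal = frozenset(f"s{i}" for i in range(10))
        part = SnpPartition(universe, causal)
        assert enrichment_fold(part, causal) == pytest.approx(10.0)  # M/|C|

    def test_empty_sets_rejected(self):
        part = SnpPartition(frozenset("ab"), frozenset())
        with pytest.raises(ValueError):
            enrichment_fold(part, frozenset("a"))


class TestEnrichmentQq:
    def test_uniform_null_hugs_diagonal(self, rng):
        n = 2_000
        ids = [f"s{i}" for i in range(n)]
        summary = make_summary(ids, np.full(n, 0.1), np.full(n, 0.1), ps=rng.uniform(size=n))
        part = SnpPartition(frozenset(ids), frozenset(ids[: n // 2]))
        qq = enrichment_qq(summary, part)
        assert len(qq) == n
        dev = (qq["observed_neglog10p"] - qq["expected_quantile"]).abs()
        assert dev.quantile(0.95) < 0.5  # KS-style envelope away from the extreme tail

    def test_signal_lifts_hp_tail(self, rng):
        n = 1_000
        ids = [f"s{i}" for i in range(2 * n)]
        p_hp = rng.uniform(size=n) ** 3  # enriched small P
        p_lp = rng.uniform(size=n)
        summary = make_summary(
            ids, np.full(2 * n, 0.1), np.full(2 * n, 0.1), ps=np.r_[p_hp, p_lp]
        )
        part = SnpPartition(frozenset(ids), frozenset(ids[:n]))
        qq = enrichment_qq(summary, part)
        top = qq.groupby("group").apply(
            lambda g: g.nlargest(50, "expected_quantile")["observed_neglog10p"].mean(),
            include_groups=False,
        )
        assert top["HP"] > top["LP"]


class TestCalibration:
    def test_identity_scores(self, rng):
        y = rng.normal(size=500)
        slope, intercept = calibration_slope(y, y)
        assert slope == pytest.approx(1.0, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_independent_scores_slope_zero(self, rng):
        slope, _ = calibration_slope(rng.normal(size=5_000), rng.normal(size=5_000))
        assert abs(slope) < 0.05

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            calibration_slope(np.ones(10), np.arange(10.0))

    def test_uncorrected_prs_overdispersed_mle_closer_to_one(self, rng):
        """Winner's-curse-inflated weights overstate score spread, giving a
        calibration slope below 1; conditional-MLE weights pull it back up."""
        from prs2d.shrinkage import mle_correct

        m, n_disc, n_val = 800, 4_000, 4_000
        alpha = 1e-3
        slopes_raw, slopes_mle = [], []
        for seed in range(8):
            r = np.random.default_rng(seed)
            beta = r.normal(0, 0.02, m)
            se = 1 / np.sqrt(n_disc)
            bh = beta + r.normal(0, se, m)
            sel = 2 * stats.norm.sf(np.abs(bh) / se) < alpha
            if sel.sum() < 3:
                continue
            g = r.normal(size=(n_val, m))
            y = g @ beta + r.normal(0, np.sqrt(max(1 - (beta**2).sum(), 0.3)), n_val)
            s_raw = g[:, sel] @ bh[sel]
            s_mle = g[:, sel] @ mle_correct(bh[sel], se, alpha)
            slopes_raw.append(calibration_slope(s_raw, y)[0])
            slopes_mle.append(calibration_slope(s_mle, y)[0])
        assert np.mean(slopes_raw) < 1.0
        assert abs(np.mean(slopes_mle) - 1) < abs(np.mean(slopes_raw) - 1)


class TestRiskStratification:
    def test_random_scores_capture_q(self, rng):
        y = rng.integers(0, 2, 20_000)
        s = rng.normal(size=20_000)
        assert risk_stratification(s, y, 0.2) == pytest.approx(0.2, abs=0.02)

    def test_perfect_separation_captures_all(self):
        y = np.r_[np.ones(10), np.zeros(90)]
        s = np.r_[np.full(10, 5.0), np.zeros(90)]
        assert risk_stratification(s, y, 0.2) == 1.0

    def test_matches_binormal_oracle_at_auc_06(self, rng):
        """Scores of cases N(mu, 1) and controls N(0, 1) with mu chosen for
        AUC = 0.6; captured-case fraction checked against a Monte-Carlo
        binormal oracle computed independently here."""
        mu = np.sqrt(2) * stats.norm.ppf(0.6)
        n_case, n_ctrl, q = 30_000, 70_000, 0.1
        s = np.r_[rng.normal(mu, 1, n_case), rng.normal(0, 1, n_ctrl)]
        y = np.r_[np.ones(n_case), np.zeros(n_ctrl)]
        observed = risk_stratification(s, y, q)
        r2 = np.random.default_rng(999)
        s2 = np.r_[r2.normal(mu, 1, n_case), r2.normal(0, 1, n_ctrl)]
        cut = np.quantile(s2, 1 - q)
        oracle = np.mean(s2[:n_case] > cut)
        assert observed == pytest.approx(oracle, abs=0.02)

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError):
            risk_stratification(np.arange(5.0), np.zeros(5), 0.2)


@pytest.fixture(scope="module")
def tiny_scenario():
    cfg = SimConfig(
        n_samples=900, m_snps=300, block_size_mean=4, within_block_rho=0.8,
        n_causal=40, hp_size=80, delta=3.0, seed=77,
    )
    panel = simulate_genotype_panel(cfg)
    causal, part = assign_causal_and_hp(cfg, panel)
    eff = draw_effect_sizes(cfg, causal)
    y = simulate_trait(panel, eff, cfg)
    return panel, part, y


class TestKfold:

    def test_self_comparison_gives_zero_deltas(self, tiny_scenario):
        panel, part, y = tiny_scenario
        folds = kfold_prediction(
            panel, y, 3, baseline="1d-none", alternative="1d-none",
            grid=[0.01, 0.1, 1.0], seed=5,
        )
        assert all(f.delta == 0.0 for f in folds)

    def test_folds_partition_samples_and_are_deterministic(self, tiny_scenario):
        panel, part, y = tiny_scenario
        kwargs = dict(
            baseline="1d-none", alternative="2d-lasso", hp_ids=part.hp,
            grid=[0.01, 0.1, 1.0], seed=5,
        )
        a = kfold_prediction(panel, y, 3, **kwargs)
        b = kfold_prediction(panel, y, 3, **kwargs)
        assert [(f.r2_baseline, f.r2_alternative) for f in a] == [
            (f.r2_baseline, f.r2_alternative) for f in b
        ]
        assert len(a) == 3

    def test_bad_k_rejected(self, tiny_scenario):
        panel, part, y = tiny_scenario
        with pytest.raises(ValueError):
            kfold_prediction(panel, y, 1)
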