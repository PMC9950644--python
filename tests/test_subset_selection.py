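"""OLS, BIC and exhaustive best-subset screening against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from canopysc import subset_selection as ss
from tests.oracles import subset_screen_bruteforce


def _random_table(n, p, seed, noise=0.1, signal=None):
    """Independent standard-normal predictors x1..xp with optional planted y."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    names = [f"x{i + 1}" for i in range(p)]
    df = pd.DataFrame(X, columns=names)
    if signal is None:
        y = rng.standard_normal(n)
    else:
        y = sum(c * X[:, i] for i, c in signal.items())
        y = y + rng.normal(scale=noise, size=n)
    df["y"] = y
    return df


class TestOlsFit:
    def test_exact_linear_relationship_zero_rss(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
        beta_true = np.array([1.0, 2.0, -0.5])
        _, rss = ss.ols_fit(X, X @ beta_true)
        assert rss == pytest.approx(0.0, abs=1e-18)

    def test_intercept_only_returns_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        beta, rss = ss.ols_fit(np.ones((4, 1)), y)
        assert beta[0] == pytest.approx(y.mean())
        assert rss == pytest.approx(((y - y.mean()) ** 2).sum())

    def test_matches_normal_equation_oracle(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 3))])
        y = rng.standard_normal(50)
        beta, rss = ss.ols_fit(X, y)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(beta, oracle, atol=1e-8)
        assert rss == pytest.approx(float(((y - X @ oracle) ** 2).sum()), abs=1e-8)

    def test_rank_deficiency_and_small_n_rejected(self, rng):
        x = rng.standard_normal(20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(ValueError, match="rank deficient"):
            ss.ols_fit(X, rng.standard_normal(20))
        with pytest.raises(ValueError, match="n > k"):
            ss.ols_fit(np.ones((3, 3)), np.ones(3))


class TestBicOf:
    def test_hand_evaluated_value(self):
        # n=100, rss=100, k=2: 100*ln(1) + 2*ln(100) = 9.2103
        assert ss.bic_of(100.0, 100, 2) == pytest.approx(9.2103, abs=1e-4)

    def test_extra_parameter_costs_ln_n(self):
        for n in (30, 120):
            assert ss.bic_of(5.0, n, 4) - ss.bic_of(5.0, n, 3) == pytest.approx(
                math.log(n)
            )

    def test_parsimony_at_equal_rss(self):
        assert ss.bic_of(2.0, 50, 2) < ss.bic_of(2.0, 50, 3)

    def test_degenerate_inputs(self):
        assert ss.bic_of(0.0, 10, 2) == -np.inf
        with pytest.raises(ValueError):
            ss.bic_of(-1.0, 10, 2)
        with pytest.raises(ValueError):
            ss.bic_of(1.0, 0, 2)


class TestFullSubsetScreen:
    def test_single_candidate_identity(self):
        df = _random_table(40, 1, seed=3, signal={0: 1.0}, noise=0.0)
        rep = ss.full_subset_screen(df, ["x1"], response="y")
        assert rep.overall_best.subset == ("x1",)
        assert rep.overall_best.rss == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_randomized_enumeration_oracle(self, seed):
        df = _random_table(60, 8, seed=seed)
        rep = ss.full_subset_screen(df, [f"x{i}" for i in range(1, 9)], response="y")
        names = [f"x{i}" for i in range(1, 9)]
        oracle_subset, oracle_bic = subset_screen_bruteforce(
            df[names].to_numpy(), df["y"].to_numpy(), names
        )
        assert rep.overall_best.subset == oracle_subset
        assert rep.overall_best.bic == pytest.approx(oracle_bic, abs=1e-8)

    def test_planted_support_recovered_at_high_snr(self):
        # At high SNR the true support is always contained in the selection;
        # exact recovery is capped by BIC's overfit probability — each of
        # the 8 noise candidates sneaks in when its scale-free RSS
        # improvement (~chi2(1)) exceeds ln(100), so the exact-recovery rate
        # sits near 1 - (1 - P[chi2(1) > ln 100])^8 ~ 0.77.
        exact = contains = 0
        for seed in range(20):
            df = _random_table(
                100, 10, seed=seed, signal={0: 2.0, 2: -1.0}, noise=0.1
            )
            rep = ss.full_subset_screen(
                df, [f"x{i}" for i in range(1, 11)], response="y"
            )
            exact += rep.overall_best.subset == ("x1", "x3")
            contains += {"x1", "x3"} <= set(rep.overall_best.subset)
        assert contains == 20
        assert exact >= 12

    def test_best_per_size_monotone_in_rss(self):
        df = _random_table(80, 6, seed=9)
        rep = ss.full_subset_screen(df, [f"x{i}" for i in range(1, 7)], response="y")
        rss = [rep.best_per_size[s].rss for s in sorted(rep.best_per_size)]
        assert all(a >= b - 1e-12 for a, b in zip(rss, rss[1:]))
        assert rep.n_evaluated == 2**6 - 1

    def test_overall_best_is_min_over_sizes(self):
        df = _random_table(50, 5, seed=4)
        rep = ss.full_subset_screen(df, [f"x{i}" for i in range(1, 6)], response="y")
        assert rep.overall_best.bic == min(r.bic for r in rep.best_per_size.values())

    def test_deterministic_under_fixed_input(self):
        df = _random_table(60, 7, seed=5)
        names = [f"x{i}" for i in range(1, 8)]
        a = ss.full_subset_screen(df, names, response="y")
        b = ss.full_subset_screen(df, names, response="y")
        assert a.overall_best == b.overall_best
        assert a.to_frame().equals(b.to_frame())

    def test_noise_candidate_cannot_help_much(self):
        # adding a pure-noise column can lower best BIC by at most ~ln(n)
        df = _random_table(100, 6, seed=6, signal={0: 1.5}, noise=0.3)
        names = [f"x{i}" for i in range(1, 7)]
        base = ss.full_subset_screen(df, names[:5], response="y").overall_best.bic
        grown = ss.full_subset_screen(df, names, response="y").overall_best.bic
        assert grown >= base - math.log(100) - 1e-9
        assert grown <= base + 1e-9  # superset search can only improve or tie

    def test_pool_guard_and_bad_inputs(self, feature_table):
        with pytest.raises(ValueError, match="reduce the pool"):
            ss.full_subset_screen(
                pd.DataFrame(np.ones((3, 26)), columns=[f"c{i}" for i in range(26)]),
                [f"c{i}" for i in range(26)],
                response="c0",
            )
        with pytest.raises(ValueError, match="not in table"):
            ss.full_subset_screen(feature_table, ["nope"], response="sc")

    def test_relative_to_null_shifts_by_null_bic(self):
        df = _random_table(60, 4, seed=8)
        names = [f"x{i}" for i in range(1, 5)]
        abs_rep = ss.full_subset_screen(df, names, response="y")
        rel_rep = ss.full_subset_screen(df, names, response="y", relative_to_null=True)
        y = df["y"].to_numpy()
        null_bic = ss.bic_of(float(((y - y.mean()) ** 2).sum()), 60, 1)
        assert rel_rep.overall_best.bic == pytest.approx(
            abs_rep.overall_best.bic - null_bic
        )


class TestStandardPools:
    def test_pools_are_disjoint_in_selection(self, feature_table):
        reports = ss.screen_standard_pools(feature_table)
        from canopysc.features import TEXTURE_POOL, VI_POOL

        assert set(reports["vis"].overall_best.subset) <= set(VI_POOL)
        assert set(reports["texture"].overall_best.subset) <= set(TEXTURE_POOL)
        summary = ss.screening_summary(reports)
        assert summary["n_candidates"].tolist() == [11, 8, 19]

    def test_planted_support_in_combined_pool(self, feature_table):
        from canopysc import synthetic as syn

        hits = 0
        for seed in range(10):
            planted = syn.plant_linear_response(
                feature_table, ("ndre", "rvi"), beta=(1.0, -1.0), snr=20.0, seed=seed
            )
            rep = ss.full_subset_screen(
                planted,
                list(("ndre", "rvi", "b808_var", "b808_sec", "b808_cor", "b560")),
                response="sc",
            )
            hits += {"ndre", "rvi"} <= set(rep.overall_best.subset)
        assert hits >= 9
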