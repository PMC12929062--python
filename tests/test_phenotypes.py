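import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rhizogwas import phenotypes as ph
from rhizogwas import synthetic_data as sd


def brute_force_filter(counts, min_total, min_prev):
    """Independent two-condition filter: per-ASV loop with explicit counting."""
    import math
    keep = []
    for col in counts.columns:
        total = int(counts[col].sum())
        prevalence = int((counts[col] > 0).sum())
        if total >= min_total and prevalence >= math.ceil(min_prev * len(counts)):
            keep.append(col)
    return keep


class TestAsvFilter:
    def test_constructed_table_matches_brute_force(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(0, index=[f"s{i}" for i in range(10)],
                              columns=[f"a{j}" for j in range(6)])
        # column sums 12000 / 9999 / 10000 with prevalence 10, 8, 7; one zero ASV
        counts["a0"] = 1200                      # total 12000, prevalence 10
        counts.loc["s0":"s7", "a1"] = 1250       # total 10000, prevalence 8
        counts.loc["s0":"s6", "a2"] = 1429       # total 10003, prevalence 7
        counts.loc["s0":"s7", "a3"] = 1249       # total 9992 < 10000
        counts["a4"] = rng.integers(1000, 1300, 10)  # total ~11500, prevalence 10
        # a5 stays all-zero
        got = ph.filter_asv_table(counts, 10_000, 0.8).columns.tolist()
        assert got == brute_force_filter(counts, 10_000, 0.8)
        assert "a2" not in got      # 7 of 10 samples < ceil(0.8 * 10)
        assert "a3" not in got      # 9992 reads
        assert "a5" not in got      # zero reads

    def test_invalid_prevalence_rejected(self):
        counts = pd.DataFrame({"a": [1, 2]})
        with pytest.raises(ValueError):
            ph.filter_asv_table(counts, 0, 1.2)


class TestNormalize:
    def test_log_relative_abundance_arithmetic(self):
        counts = pd.DataFrame({"a": [5], "b": [45]}, index=["s1"])
        fm = ph.normalize_asv_abundance(counts, pseudocount=1e-6)
        assert fm.values[0, 0] == pytest.approx(np.log(0.1 + 1e-6))

    def test_equal_counts_get_equal_values(self):
        counts = pd.DataFrame({"a": [30], "b": [30]}, index=["s1"])
        fm = ph.normalize_asv_abundance(counts)
        assert fm.values[0, 0] == fm.values[0, 1]

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"a": [0], "b": [0]}, index=["s1"])
        with pytest.raises(ValueError, match="zero total"):
            ph.normalize_asv_abundance(counts)


def dense_reml_loglik(y, X, Z_list, gammas):
    """Independent dense restricted likelihood (profiled scale) on small data."""
    n, p = X.shape
    H = np.eye(n)
    for g, Z in zip(gammas, Z_list):
        H += g * (Z @ Z.T)
    Hi = np.linalg.inv(H)
    XtHX = X.T @ Hi @ X
    beta = np.linalg.solve(XtHX, X.T @ Hi @ y)
    r = y - X @ beta
    yPy = float(r @ Hi @ r)
    df = n - p
    return -0.5 * (df * np.log(yPy / df) + np.log(np.linalg.det(H))
                   + np.log(np.linalg.det(XtHX))
                   + df * (1.0 + np.log(2.0 * np.pi)))


class TestPlotLmm:
    def test_constant_values_give_zero_variances(self):
        df = pd.DataFrame({
            "genotype": ["g1", "g2"] * 3, "environment": "E",
            "replicate": ["r1", "r1", "r2", "r2", "r3", "r3"],
            "block": "b1", "value": 5.0,
        })
        vc = ph.fit_plot_lmm(df, "E")
        assert vc.sigma_g2 == 0 and vc.sigma_r2 == 0 and vc.sigma_b2 == 0
        assert vc.sigma_e2 > 0

    def test_parameter_recovery_on_balanced_design(self):
        """Mean REML estimates over replicate simulations track the truth
        (sigma_g2 = 2, sigma_e2 = 1) within 10%."""
        sg2, se2 = [], []
        for rep in range(8):
            rng = np.random.default_rng(100 + rep)
            g = rng.normal(0, np.sqrt(2.0), 150)
            rows = []
            for j in range(3):
                for i in range(150):
                    rows.append((f"g{i}", "E", f"r{j}", "b0",
                                 g[i] + rng.normal(0, 1.0)))
            df = pd.DataFrame(rows, columns=["genotype", "environment",
                                             "replicate", "block", "value"])
            vc = ph.fit_plot_lmm(df, "E")
            sg2.append(vc.sigma_g2)
            se2.append(vc.sigma_e2)
        assert np.mean(sg2) == pytest.approx(2.0, rel=0.10)
        assert np.mean(se2) == pytest.approx(1.0, rel=0.10)

    def test_permuted_genotype_labels_kill_genetic_variance(self):
        rng = np.random.default_rng(5)
        g = rng.normal(0, np.sqrt(2.0), 100)
        rows = []
        for j in range(3):
            perm = rng.permutation(100)
            for i in range(100):
                rows.append((f"g{perm[i]}", "E", f"r{j}", "b0",
                             g[i] + rng.normal(0, 1.0)))
        df = pd.DataFrame(rows, columns=["genotype", "environment",
                                         "replicate", "block", "value"])
        vc = ph.fit_plot_lmm(df, "E")
        assert vc.sigma_g2 < 0.25 * vc.sigma_e2

    def test_matches_dense_grid_oracle_on_tiny_instance(self):
        """On <= 12 observations the Woodbury REML optimum beats (to 1e-4)
        every point of a dense restricted-likelihood grid."""
        rng = np.random.default_rng(42)
        df = pd.DataFrame({
            "genotype": ["g1", "g2", "g3", "g4"] * 3,
            "environment": "E",
            "replicate": np.repeat(["r1", "r2", "r3"], 4),
            "block": np.repeat(["b1", "b2", "b3"], 4),
            "value": rng.normal(0, 1, 12) + np.tile([0.0, 1.0, 2.0, 3.0], 3),
        })
        vc = ph.fit_plot_lmm(df, "E")
        y = df["value"].to_numpy()
        X = np.ones((12, 1))
        Zg = pd.get_dummies(df["genotype"]).to_numpy(float)
        Zr = pd.get_dummies(df["replicate"]).to_numpy(float)
        Zb = pd.get_dummies(df["replicate"] + df["block"]).to_numpy(float)
        grid = [0.0] + list(np.logspace(-3, 2, 8))
        best_grid = max(
            dense_reml_loglik(y, X, [Zg, Zr, Zb], gam)
            for gam in itertools.product(grid, repeat=3)
        )
        assert vc.loglik >= best_grid - 1e-4

    def test_single_observation_rejected(self):
        df = pd.DataFrame({"genotype": ["g1"], "environment": "E",
                           "replicate": ["r1"], "block": ["b1"], "value": [1.0]})
        with pytest.raises(ph.FitError):
            ph.fit_plot_lmm(df, "E")


class TestHeritability:
    def test_formula(self):
        vc = ph.VarianceComponents(2.0, 0.0, 0.0, 3.0, 0.0, 3)
        assert ph.estimate_h2(vc) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_limits(self):
        assert ph.estimate_h2(ph.VarianceComponents(0.0, 0, 0, 1.0, 0, 3)) == 0.0
        assert ph.estimate_h2(
            ph.VarianceComponents(1.0, 0, 0, 1e-12, 0, 3)
        ) == pytest.approx(1.0, abs=1e-9)

    def test_null_features_rarely_pass_screen(self):
        """Traits with zero genotypic variance pass H2 > 0.15 in at most 10%
        of simulations at the panel size of the study."""
        cfg = sd.SimulationConfig(n_genotypes=175)
        passed = 0
        n_sims = 20
        for s in range(n_sims):
            gv = pd.Series(np.zeros(175), index=[f"G{i:03d}" for i in range(175)])
            plot = sd.simulate_field_trial(gv, cfg, sigma_e2=1.0, seed=900 + s)
            h2 = ph.estimate_h2(ph.fit_plot_lmm(plot, "E1"))
            passed += h2 > 0.15
        assert passed <= 0.10 * n_sims


class TestBlues:
    def test_balanced_design_equals_genotype_means(self, toy_plot_table):
        blues = ph.compute_blues(toy_plot_table, "KF")
        means = toy_plot_table.groupby("genotype")["value"].mean()
        np.testing.assert_allclose(blues[means.index], means, atol=1e-8)

    def test_unbalanced_design_matches_normal_equations(self):
        """With one missing plot, BLUEs equal the direct GLS solve under the
        same fitted covariance."""
        rng = np.random.default_rng(8)
        rows = []
        for rep in ("r1", "r2", "r3"):
            for i in range(10):
                if rep == "r3" and i == 0:
                    continue  # genotype g0 loses one replicate
                rows.append((f"g{i}", "KF", rep, "b1",
                             i * 0.5 + {"r1": 0.3, "r2": -0.2, "r3": 0.1}[rep]
                             + rng.normal(0, 0.2)))
        df = pd.DataFrame(rows, columns=["genotype", "environment",
                                         "replicate", "block", "value"])
        blues = ph.compute_blues(df, "KF")

        # independent dense GLS at the same variance ratios
        vc_rows = df.copy()
        y = vc_rows["value"].to_numpy()
        X = pd.get_dummies(vc_rows["genotype"]).to_numpy(float)
        Zr = pd.get_dummies(vc_rows["replicate"]).to_numpy(float)
        Zb = pd.get_dummies(vc_rows["replicate"] + vc_rows["block"]).to_numpy(float)
        ws = ph._RemlWorkspace(y, X, [Zr, Zb])
        gammas, _, _, _ = ph._reml_optimize(ws, 2)
        H = np.eye(len(y)) + gammas[0] * Zr @ Zr.T + gammas[1] * Zb @ Zb.T
        Hi = np.linalg.inv(H)
        beta = np.linalg.solve(X.T @ Hi @ X, X.T @ Hi @ y)
        np.testing.assert_allclose(blues.to_numpy(), beta, atol=1e-6)


def blom_oracle(x):
    """Independent rank + quantile oracle with tie averaging."""
    n = len(x)
    scores = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    order = np.argsort(x, kind="mergesort")
    out = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and x[order[j]] == x[order[i]]:
            j += 1
        out[order[i:j]] = scores[i:j].mean()
        i = j
    return out


class TestQQNorm:
    def test_three_values_symmetric(self):
        out = ph.qqnorm_transform(np.array([1.0, 2.0, 3.0]))
        assert out[1] == pytest.approx(0.0, abs=1e-12)
        assert out[0] == pytest.approx(-out[2])

    def test_tied_values_average_scores(self):
        x = np.array([5.0, 1.0, 1.0, 9.0])
        np.testing.assert_allclose(ph.qqnorm_transform(x), blom_oracle(x), atol=1e-12)
        # frozen values from the oracle
        np.testing.assert_allclose(
            ph.qqnorm_transform(x),
            [0.29931, -0.67422, -0.67422, 1.04913], atol=1e-4,
        )

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=50)
           .filter(lambda v: len(set(v)) > 1))
    def test_monotone_and_centred(self, values):
        x = np.asarray(values)
        out = ph.qqnorm_transform(x)
        order = np.argsort(x, kind="mergesort")
        assert np.all(np.diff(out[order]) >= -1e-12)
        np.testing.assert_allclose(ph.qqnorm_transform(x), blom_oracle(x), atol=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            ph.qqnorm_transform(np.array([2.0, 2.0, 2.0]))
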