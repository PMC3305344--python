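"""Descriptor summary statistics and Varimax factor analysis."""

import numpy as np
import pandas as pd
import pytest

from metachem.chemspace import (
    era_comparison,
    factor_analysis_varimax,
    summarize_and_test,
    varimax,
)


def _two_factor_data(n=1000, p=10, sigma=0.15, seed=42):
    """Exact two-factor model with simple-structure loadings + small noise.

    Returns the data frame and the analytically standardized generating
    loadings (each variable's loading over its total standard deviation).
    """
    rng = np.random.default_rng(seed)
    L = np.zeros((p, 2))
    L[: p // 2, 0] = np.linspace(0.85, 0.95, p // 2)
    L[p // 2:, 1] = np.linspace(0.85, 0.95, p - p // 2)
    F = rng.normal(size=(n, 2))
    X = F @ L.T + sigma * rng.normal(size=(n, p))
    expected = L / np.sqrt((L**2).sum(axis=1) + sigma**2)[:, None]
    return pd.DataFrame(X, columns=[f"d{i}" for i in range(p)]), expected


def loading_error(L, expected):
    """Max |difference| up to factor sign and permutation."""
    best = np.inf
    for perm in ([0, 1], [1, 0]):
        for s1 in (1, -1):
            for s2 in (1, -1):
                M = L[:, perm] * np.array([s1, s2])
                best = min(best, np.abs(M - expected).max())
    return best


class TestSummarize:
    def test_identical_samples(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        t = summarize_and_test(a, a.copy())
        assert (t["mean_a"] == t["mean_b"]).all()
        assert (t["p_value"] > 0.99).all()

    def test_shifted_descriptor_detected(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame({"x": rng.normal(0, 1, 200), "y": rng.normal(0, 1, 200)})
        b = pd.DataFrame({"x": rng.normal(2, 1, 200), "y": rng.normal(0, 1, 200)})
        t = summarize_and_test(a, b)
        assert t.loc["x", "p_value"] < 1e-6
        assert t.loc["y", "p_value"] > 0.01

    def test_median_definition(self):
        a = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        b = pd.DataFrame({"x": [0.0, 0.0]})
        assert summarize_and_test(a, b).loc["x", "median_a"] == 2.5

    def test_zero_variance_flagged_p_one(self):
        a = pd.DataFrame({"x": [1.0] * 5})
        b = pd.DataFrame({"x": [1.0] * 5})
        t = summarize_and_test(a, b)
        assert t.loc["x", "p_value"] == 1.0
        assert bool(t.loc["x", "zero_variance"])

    def test_minimum_rows(self):
        a = pd.DataFrame({"x": [1.0]})
        with pytest.raises(ValueError):
            summarize_and_test(a, a)

    def test_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        b = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        t = summarize_and_test(a, b)
        assert (t["p_bonferroni"] >= t["p_value"] - 1e-12).all()


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        L = np.zeros((8, 2))
        L[:4, 0] = [0.9, 0.8, 0.85, 0.95]
        L[4:, 1] = [0.9, 0.8, 0.85, 0.95]
        rotated, R = varimax(L)
        assert np.abs(np.abs(R) - np.eye(2)).max() < 0.01
        assert np.abs(np.abs(rotated) - np.abs(L)).max() < 0.01

    def test_rotation_is_orthogonal(self):
        rng = np.random.default_rng(3)
        L = rng.normal(size=(10, 2))
        _, R = varimax(L)
        assert np.allclose(R.T @ R, np.eye(2), atol=1e-10)

    def test_agrees_with_bruteforce_angle_search(self):
        """For 2 factors, varimax reduces to a 1D rotation-angle search."""
        rng = np.random.default_rng(4)
        L = rng.normal(size=(12, 2))
        comm = np.sqrt((L**2).sum(axis=1))
        Ln = L / comm[:, None]

        def criterion(M):
            sq = M**2
            return (sq**2).sum(axis=0) - (sq.sum(axis=0) ** 2) / M.shape[0]

        best = -np.inf
        for theta in np.linspace(0, np.pi / 2, 200001):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s], [s, c]])
            v = criterion(Ln @ R).sum()
            if v > best:
                best = v
        rotated, _ = varimax(L, normalize=True)
        got = criterion(rotated / comm[:, None]).sum()
        assert got == pytest.approx(best, abs=1e-6)


class TestFactorAnalysis:
    def test_planted_two_factor_recovery(self):
        df, expected = _two_factor_data()
        model = factor_analysis_varimax(df)
        err = loading_error(model.loadings.to_numpy(), expected)
        assert err < 0.05

    def test_variance_conservation_under_rotation(self):
        df, _ = _two_factor_data(seed=7)
        model = factor_analysis_varimax(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        corr = np.corrcoef(Z.to_numpy(), rowvar=False)
        ev = np.sort(np.linalg.eigvalsh(corr))[::-1][:2]
        unrotated_pct = ev.sum() / df.shape[1] * 100
        assert model.total_variance_explained == pytest.approx(unrotated_pct, abs=1e-9)

    def test_variance_explained_in_range(self):
        df, _ = _two_factor_data(seed=8)
        model = factor_analysis_varimax(df)
        for v in model.variance_explained:
            assert 0 < v <= 100

    def test_constant_column_dropped(self):
        df, _ = _two_factor_data()
        df["const"] = 1.0
        model = factor_analysis_varimax(df)
        assert "const" in model.dropped
        assert "const" not in model.loadings.index

    def test_scores_invariant_to_row_order_up_to_sign(self):
        df, _ = _two_factor_data(seed=9)
        model = factor_analysis_varimax(df)
        perm = np.random.default_rng(0).permutation(len(df))
        model_p = factor_analysis_varimax(df.iloc[perm])
        a = model.scores.loc[df.index[perm[0]]].to_numpy()
        b = model_p.scores.loc[df.index[perm[0]]].to_numpy()
        for pcols in ([0, 1], [1, 0]):
            if np.allclose(np.abs(a), np.abs(b[pcols]), atol=1e-6):
                break
        else:
            pytest.fail("scores changed under row permutation")

    def test_requires_enough_rows(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 8)))
        with pytest.raises(ValueError):
            factor_analysis_varimax(df)

    def test_high_loading_descriptors_reported(self):
        df, expected = _two_factor_data(sigma=0.05)
        model = factor_analysis_varimax(df)
        named = set(model.high_loading_descriptors[0]) | set(model.high_loading_descriptors[1])
        assert named == set(df.columns)  # every variable loads > 0.85 somewhere


class TestEraComparison:
    def test_polarity_shifted_class_separates(self):
        rng = np.random.default_rng(10)
        n = 300
        df, _ = _two_factor_data(n=2 * n, seed=10)
        # plant a factor-1 shift in the "early" half via its loading variables
        labels = np.array(["early"] * n + ["late"] * n)
        df.iloc[:n, :5] += 1.5
        table, summary = era_comparison(df, labels)
        assert abs(summary["factor1_smd"]) > 1

    def test_identical_classes_no_separation(self):
        df, _ = _two_factor_data(seed=11)
        labels = np.array(["early", "late"] * (len(df) // 2))
        _, summary = era_comparison(df, labels)
        assert abs(summary["factor1_smd"]) < 0.2

    def test_label_permutation_collapses_separation(self):
        rng = np.random.default_rng(12)
        n = 150
        df, _ = _two_factor_data(n=2 * n, seed=12)
        df.iloc[:n, :5] += 1.5
        labels = np.array(["early"] * n + ["late"] * n)
        _, real = era_comparison(df, labels)
        model = factor_analysis_varimax(df)
        smds = []
        for _ in range(100):
            perm = rng.permutation(labels)
            _, s = era_comparison(df, perm, model=model)
            smds.append(abs(s["factor1_smd"]))
        assert np.mean(smds) < abs(real["factor1_smd"]) / 5

    def test_small_class_skips_tests(self):
        df, _ = _two_factor_data(seed=13)
        labels = np.array(["early"] + ["late"] * (len(df) - 1))
        table, _ = era_comparison(df, labels)
        assert "tests_skipped" in table.columns
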