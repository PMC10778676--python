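"""Tests for group comparison letters, correlation screening and PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ricegi import (
    GeneratorConfig,
    compact_letter_display,
    compare_groups,
    correlation_report,
    generate_variety_table,
    pca,
)
from ricegi.config import VARIABLES

from oracles import tukey_kramer_pvalues


def group_frame(groups: dict[str, np.ndarray], var: str = "y") -> pd.DataFrame:
    rows = [{"type": g, var: float(v)} for g, vals in groups.items() for v in vals]
    df = pd.DataFrame(rows)
    df["variety"] = [f"v{i}" for i in range(len(df))]
    return df


class TestCompareGroups:
    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        groups = {g: m + rng.normal(0, 0.1, 5) for g, m in
                  [("g1", 0.0), ("g2", 10.0), ("g3", 20.0)]}
        res = compare_groups(group_frame(groups), variables=["y"])
        letters = res.summary.loc["y"]["letters"]
        assert sorted(letters.tolist()) == ["a", "b", "c"]
        # highest mean gets 'a'
        assert letters["g3"] == "a"

    def test_letters_match_bruteforce_significance(self):
        """Sharing a letter <=> pairwise Tukey-Kramer p > alpha (oracle)."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            k = int(rng.integers(3, 7))
            names = [f"g{i}" for i in range(k)]
            groups = {
                g: rng.normal(rng.uniform(0, 3), rng.uniform(0.5, 2.0),
                              int(rng.integers(3, 9)))
                for g in names
            }
            res = compare_groups(group_frame(groups), variables=["y"])
            letters = res.summary.loc["y"]["letters"]
            p_oracle = tukey_kramer_pvalues([groups[g] for g in names])
            for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
                shares = bool(set(letters[a]) & set(letters[b]))
                assert shares == (p_oracle[i, j] > 0.05), (
                    f"{a}/{b}: letters {letters[a]}/{letters[b]}, "
                    f"oracle p={p_oracle[i, j]:.4f}")

    def test_null_simulation_type_one_rate(self):
        """Under identical means, all groups share a letter with prob ~ 1-alpha."""
        rng = np.random.default_rng(2024)
        all_merged = 0
        reps = 150
        for _ in range(reps):
            groups = {f"g{i}": rng.normal(0.0, 1.0, 6) for i in range(5)}
            res = compare_groups(group_frame(groups), variables=["y"])
            letters = res.summary.loc["y"]["letters"]
            if set.intersection(*(set(s) for s in letters)):
                all_merged += 1
        assert 0.89 <= all_merged / reps <= 1.0

    def test_singleton_group_reported_without_letter(self):
        rng = np.random.default_rng(3)
        groups = {"a": rng.normal(0, 1, 5), "b": rng.normal(5, 1, 5),
                  "solo": np.array([2.0])}
        res = compare_groups(group_frame(groups), variables=["y"])
        row = res.summary.loc[("y", "solo")]
        assert row["letters"] == "" and row["n"] == 1 and row["mean"] == 2.0

    def test_too_few_groups_rejected(self):
        df = group_frame({"only": np.arange(5.0)})
        with pytest.raises(ValueError):
            compare_groups(df, variables=["y"])

    def test_zero_variance_merges_all(self):
        df = group_frame({"a": np.full(4, 1.0), "b": np.full(4, 1.0)})
        with pytest.warns(RuntimeWarning):
            res = compare_groups(df, variables=["y"])
        letters = res.summary.loc["y"]["letters"]
        assert set(letters) == {"a"}


class TestCLD:
    def test_insert_and_absorb_chain(self):
        # a > b > c with only a-c significant: a/ab/b pattern
        letters = compact_letter_display(
            {"a": 3.0, "b": 2.0, "c": 1.0}, {frozenset(("a", "c"))})
        assert set(letters["b"]) == set(letters["a"]) | set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])

    def test_all_significant_all_distinct(self):
        means = {"x": 3.0, "y": 2.0, "z": 1.0}
        sig = {frozenset(p) for p in itertools.combinations(means, 2)}
        letters = compact_letter_display(means, sig)
        assert sorted(letters.values()) == ["a", "b", "c"]


class TestCorrelation:
    def test_duplicated_column_perfectly_correlated(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["y"] = df["x"]
        rep = correlation_report(df, variables=["x", "y"])
        assert rep.r.loc["x", "y"] == pytest.approx(1.0)
        assert bool(rep.significant.loc["x", "y"])

    def test_independent_columns_mostly_masked(self):
        rng = np.random.default_rng(5)
        reps, flagged = 400, 0
        for _ in range(reps):
            df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["x", "y"])
            rep = correlation_report(df, variables=["x", "y"])
            flagged += bool(rep.significant.loc["x", "y"])
        assert flagged / reps == pytest.approx(0.05, abs=0.03)

    def test_generator_round_trip_strong_negative(self):
        cfg = GeneratorConfig(
            n_varieties=200, type_counts={"Long A": 200}, seed=17)
        table = generate_variety_table(cfg)
        rep = correlation_report(table)
        assert rep.r.loc["RS", "eGI"] == pytest.approx(-0.9, abs=0.05)
        assert bool(rep.significant.loc["RS", "eGI"])

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"x": np.ones(20), "y": np.arange(20.0)})
        rep = correlation_report(df, variables=["x", "y"])
        assert np.isnan(rep.r.loc["x", "y"])
        assert not bool(rep.significant.loc["x", "y"])

    def test_symmetry_and_unit_diagonal(self):
        cfg = GeneratorConfig(seed=6)
        table = generate_variety_table(cfg)
        rep = correlation_report(table)
        assert np.allclose(rep.r, rep.r.T, equal_nan=True)
        assert np.allclose(np.diag(rep.r), 1.0)
        assert rep.r.abs().max().max() <= 1.0 + 1e-12


class TestPCA:
    def test_variance_fractions_and_reconstruction(self):
        cfg = GeneratorConfig(seed=8)
        table = generate_variety_table(cfg)
        res = pca(table)
        assert res.variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.variance_ratio) <= 1e-12)
        x = table.set_index("variety")[list(VARIABLES)].to_numpy(float)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.max(np.abs(recon - z)) <= 1e-8

    def test_loadings_orthonormal_and_sign_fixed(self):
        table = generate_variety_table(GeneratorConfig(seed=9))
        res = pca(table)
        load = res.loadings.to_numpy()
        assert np.allclose(load.T @ load, np.eye(load.shape[1]), atol=1e-8)
        for col in load.T:
            assert col[np.argmax(np.abs(col))] > 0

    def test_single_factor_dominates(self):
        """One latent factor (loading 0.9 everywhere) concentrates variance in PC1."""
        corr = np.full((16, 16), 0.81)
        np.fill_diagonal(corr, 1.0)
        cfg = GeneratorConfig(
            n_varieties=200, type_counts={"Long A": 200},
            target_correlation=corr, seed=10)
        table = generate_variety_table(cfg)
        res = pca(table)
        oracle_share = np.linalg.eigvalsh(corr)[-1] / 16.0
        assert res.variance_ratio[0] > oracle_share - 0.05
        assert res.variance_ratio[0] > 0.7

    def test_duplicated_rows_identical_scores(self):
        table = generate_variety_table(GeneratorConfig(seed=12))
        doubled = pd.concat([table, table.assign(variety=table["variety"] + "_dup")],
                            ignore_index=True)
        res = pca(doubled)
        s = res.scores
        assert np.allclose(s.loc["LA01"], s.loc["LA01_dup"])

    def test_zero_variance_column_rejected(self):
        table = generate_variety_table(GeneratorConfig(seed=13))
        table["FAT"] = 1.0
        with pytest.raises(ValueError, match="FAT"):
            pca(table)
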