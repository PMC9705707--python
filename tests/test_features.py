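"""Pairwise Spearman profiles and inside/outside feature statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cyspaint import (
    ComparisonMatrix,
    ConfigurationError,
    edge_inside_outside_means,
    feature_test,
    inside_outside_means,
    pairwise_spearman,
    profile_degree_correlation,
    significance_stars,
)
from cyspaint import test_features as run_feature_screen

from test_scaling import t_tail_df2


def make_matrix(profiles: dict[str, list[float]], changed: dict[str, list[bool]] | None = None):
    ratios = pd.DataFrame(profiles).T
    stimuli = [f"s{i + 1}" for i in range(ratios.shape[1])]
    ratios.columns = stimuli
    if changed is None:
        flags = pd.DataFrame(True, index=ratios.index, columns=stimuli)
    else:
        flags = pd.DataFrame(changed).T
        flags.columns = stimuli
    return ComparisonMatrix(ratios=ratios, changed=flags, stimuli=stimuli)


def spearman_rank_formula(x, y):
    """No-ties oracle: R_s = 1 - 6 sum(d^2) / (n (n^2 - 1))."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = np.sum((rx - ry) ** 2)
    n = len(x)
    return 1 - 6 * d2 / (n * (n ** 2 - 1))


class TestPairwiseSpearman:
    def test_monotone_profiles_correlate_perfectly(self):
        matrix = make_matrix({"A": [1, 2, 3, 4, 5], "B": [2, 4, 6, 8, 10]})
        pairs = pairwise_spearman(matrix)
        assert pairs["rs"].iloc[0] == pytest.approx(1.0)

    def test_reversed_profiles_correlate_negatively(self):
        matrix = make_matrix({"A": [1, 2, 3], "B": [3, 2, 1]})
        pairs = pairwise_spearman(matrix)
        assert pairs["rs"].iloc[0] == pytest.approx(-1.0)
        assert pairs["abs_rs"].iloc[0] == pytest.approx(1.0)

    def test_worked_example_matches_rank_formula(self):
        x = [0.5, -0.2, 0.9, 0.1, -0.6]
        y = [0.3, 0.0, 0.8, -0.1, 0.2]
        matrix = make_matrix({"A": x, "B": y})
        pairs = pairwise_spearman(matrix)
        assert pairs["rs"].iloc[0] == pytest.approx(0.6)
        assert pairs["rs"].iloc[0] == pytest.approx(spearman_rank_formula(x, y))

    def test_requires_three_stimuli(self):
        matrix = make_matrix({"A": [1, 2], "B": [2, 1]})
        with pytest.raises(ConfigurationError):
            pairwise_spearman(matrix)

    def test_zero_variance_profile_is_excluded(self):
        matrix = make_matrix({"A": [1, 1, 1], "B": [1, 2, 3], "C": [3, 1, 2]})
        pairs = pairwise_spearman(matrix)
        assert set(zip(pairs["protein_a"], pairs["protein_b"])) == {("B", "C")}

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=5), rng.normal(size=5)
        base = pairwise_spearman(make_matrix({"A": x, "B": y}))["rs"].iloc[0]
        warped = pairwise_spearman(
            make_matrix({"A": np.exp(2 * x), "B": y}))["rs"].iloc[0]
        assert warped == pytest.approx(base)


ABS_RS = {("A", "B"): 0.8, ("A", "C"): 0.6, ("B", "C"): 0.4,
          ("A", "D"): 0.2, ("B", "D"): 0.3, ("C", "D"): 0.1}


def pairs_from_dict(values=ABS_RS):
    return pd.DataFrame([(a, b, v, abs(v)) for (a, b), v in values.items()],
                        columns=["protein_a", "protein_b", "rs", "abs_rs"])


class TestInsideOutsideMeans:
    def test_enumeration_example(self):
        out = inside_outside_means(pairs_from_dict(), {"A", "B", "C"})
        expected = {"A": (0.7, 0.2), "B": (0.6, 0.3), "C": (0.5, 0.1)}
        assert set(out["protein"]) == set(expected)
        for _, row in out.iterrows():
            inside, outside = expected[row["protein"]]
            assert row["inside_mean"] == pytest.approx(inside)
            assert row["outside_mean"] == pytest.approx(outside)

    def test_feature_with_all_proteins_has_no_outside_bin(self):
        out = inside_outside_means(pairs_from_dict(), {"A", "B", "C", "D"})
        assert out.empty

    def test_feature_with_single_member_has_no_inside_bin(self):
        out = inside_outside_means(pairs_from_dict(), {"A"})
        assert out.empty

    def test_discarding_neither_member_pairs_changes_nothing(self):
        members = {"A", "B"}
        full = inside_outside_means(pairs_from_dict(), members)
        trimmed_pairs = pairs_from_dict(
            {k: v for k, v in ABS_RS.items() if set(k) & members})
        trimmed = inside_outside_means(trimmed_pairs, members)
        pd.testing.assert_frame_equal(full, trimmed)

    def test_edge_feature_bins_by_shared_edge(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        out = edge_inside_outside_means(pairs_from_dict(), g)
        a = out[out["protein"] == "A"].iloc[0]
        # inside: AB (edge); outside: AC, AD (no edge)
        assert a["inside_mean"] == pytest.approx(0.8)
        assert a["outside_mean"] == pytest.approx((0.6 + 0.2) / 2)


class TestFeatureTest:
    def test_worked_example_matches_df2_closed_form(self):
        per_protein = pd.DataFrame({
            "protein": ["A", "B", "C"],
            "inside_mean": [0.8, 0.7, 0.9],
            "outside_mean": [0.5, 0.5, 0.5],
        })
        result = feature_test(per_protein, "f")
        assert result.t == pytest.approx(5.196, abs=1e-3)
        assert result.p == pytest.approx(t_tail_df2(result.t), rel=1e-9)
        assert result.p == pytest.approx(0.0351, abs=1e-4)
        assert result.stars == "*"

    def test_sign_flip_negates_t_and_keeps_p(self):
        forward = pd.DataFrame({"protein": list("ABC"),
                                "inside_mean": [0.8, 0.7, 0.9],
                                "outside_mean": [0.5, 0.5, 0.5]})
        backward = forward.rename(columns={"inside_mean": "outside_mean",
                                           "outside_mean": "inside_mean"})
        r1, r2 = feature_test(forward, "f"), feature_test(backward, "f")
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_equal_means_everywhere_is_degenerate(self):
        per_protein = pd.DataFrame({"protein": list("ABC"),
                                    "inside_mean": [0.5, 0.6, 0.7],
                                    "outside_mean": [0.5, 0.6, 0.7]})
        result = feature_test(per_protein, "f")
        assert result.degenerate
        assert np.isnan(result.p)

    def test_fewer_than_three_members_skips_the_test(self):
        per_protein = pd.DataFrame({"protein": ["A", "B"],
                                    "inside_mean": [0.8, 0.7],
                                    "outside_mean": [0.5, 0.5]})
        assert feature_test(per_protein, "f") is None

    def test_welch_mode_runs(self):
        per_protein = pd.DataFrame({"protein": list("ABCD"),
                                    "inside_mean": [0.8, 0.7, 0.9, 0.85],
                                    "outside_mean": [0.5, 0.45, 0.55, 0.5]})
        result = feature_test(per_protein, "f", mode="welch")
        assert result.p < 0.01

    @pytest.mark.parametrize("p,expected", [
        (0.2, ""), (0.04, "*"), (0.009, "**"), (0.0009, "***"), (float("nan"), "")])
    def test_star_notation(self, p, expected):
        assert significance_stars(p) == expected


class TestTestFeatures:
    def test_shared_latent_profile_raises_inside_correlation(self):
        rng = np.random.default_rng(7)
        latent = rng.normal(0, 1.5, size=5)
        profiles = {f"M{i}": latent + rng.normal(0, 0.2, 5) for i in range(8)}
        profiles.update({f"X{i}": rng.normal(0, 1.5, 5) for i in range(12)})
        matrix = make_matrix(profiles)
        pairs = pairwise_spearman(matrix)
        table = run_feature_screen(pairs, {"complex": {f"M{i}" for i in range(8)}})
        row = table.iloc[0]
        assert row["inside_mean"] > row["outside_mean"]
        assert row["p"] < 0.05
        assert "p_bh" in table.columns

    def test_untestable_features_are_skipped(self):
        table = run_feature_screen(pairs_from_dict(), {"tiny": {"A"}, "ok": {"A", "B", "C"}})
        assert table["feature"].tolist() == ["ok"]


class TestProfileDegreeCorrelation:
    def test_all_degrees_equal_is_undefined(self):
        matrix = make_matrix({"A": [1, 2, 3], "B": [2, 1, 3]},
                             changed={"A": [1, 0, 0], "B": [0, 1, 0]})
        rs, n = profile_degree_correlation(matrix)
        assert np.isnan(rs)
        assert n == 6

    def test_magnitude_increasing_with_degree_gives_one(self):
        matrix = make_matrix(
            {"A": [0.1, 0.2, 0.3], "B": [1.1, 1.2, 1.3], "C": [2.1, 2.2, 2.3]},
            changed={"A": [1, 0, 0], "B": [1, 1, 0], "C": [1, 1, 1]})
        rs, _ = profile_degree_correlation(matrix)
        assert rs > 0.9

    def test_toy_matrix_matches_scipy_oracle(self):
        from scipy import stats
        matrix = make_matrix(
            {"A": [0.5, -0.2, 0.9], "B": [1.5, 0.1, -0.3]},
            changed={"A": [1, 0, 0], "B": [1, 1, 0]})
        rs, n = profile_degree_correlation(matrix)
        mags = [0.5, 0.2, 0.9, 1.5, 0.1, 0.3]
        degs = [1, 1, 1, 2, 2, 2]
        assert n == 6
        assert rs == pytest.approx(stats.spearmanr(mags, degs).statistic)
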