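"""Rank tests against enumeration oracles; BH-FDR properties; baseline table.

The exact Mann-Whitney oracle enumerates all C(n, n_A) assignments of the
pooled ranks to group A; the signed-rank oracle enumerates all 2^n sign
patterns of the absolute differences.
"""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from radrepro import (
    ReconstructionDesign,
    baseline_comparison,
    fdr_adjust,
    mann_whitney,
    pairwise_algorithm_counts,
    signed_rank,
    simulate,
    get_preset,
)
from conftest import make_table


# ---------------------------------------------------------------------- #
def mann_whitney_exact_oracle(a, b):
    """Two-sided p by full enumeration of group assignments (no ties)."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = pooled.argsort().argsort() + 1
    u_obs = np.sum(ranks[:na]) - na * (na + 1) / 2
    mean_u = na * (n - na) / 2
    count = 0
    total = 0
    for idx in combinations(range(n), na):
        u = np.sum(ranks[list(idx)]) - na * (na + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


def signed_rank_exact_oracle(d):
    """Two-sided p by enumeration of all sign patterns (no ties, no zeros)."""
    d = np.asarray(d, dtype=float)
    ranks = np.abs(d).argsort().argsort() + 1
    w_obs = np.sum(ranks[d > 0])
    mean_w = ranks.sum() / 2
    count = total = 0
    for signs in product([0, 1], repeat=len(d)):
        w = np.sum(ranks[np.array(signs, dtype=bool)])
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        out = mann_whitney([1, 2, 3], [1, 2, 3])
        assert out.p_value >= 0.98

    def test_fully_separated_small_groups(self):
        # U = 0; two-sided p = 2 / C(6,3) = 0.1
        out = mann_whitney([1, 2, 3], [10, 11, 12])
        assert out.method == "exact"
        assert out.p_value == pytest.approx(0.1, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na = int(rng.integers(2, 5))
        nb = int(rng.integers(2, 5))
        pooled = rng.permutation(np.arange(1.0, na + nb + 1))  # tie-free
        a, b = pooled[:na], pooled[na:]
        out = mann_whitney(a, b)
        assert out.method == "exact"
        assert out.p_value == pytest.approx(mann_whitney_exact_oracle(a, b), abs=1e-12)


class TestSignedRank:
    def test_all_zero_diffs_degenerate(self):
        out = signed_rank([0.0, 0.0, 0.0])
        assert out.degenerate and out.p_value == 1.0

    def test_all_positive_five_diffs(self):
        # 2 / 2^5
        out = signed_rank([1, 2, 3, 4, 5])
        assert out.method == "exact"
        assert out.p_value == pytest.approx(0.0625, abs=1e-12)

    def test_zeros_dropped_before_ranking(self):
        with_zeros = signed_rank([0.0, 1, 2, 3, 4, 5, 0.0])
        without = signed_rank([1, 2, 3, 4, 5])
        assert with_zeros.p_value == pytest.approx(without.p_value, abs=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_path_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 11))
        d = rng.permutation(np.arange(1.0, n + 1)) * rng.choice([-1, 1], size=n)
        out = signed_rank(d)
        assert out.method == "exact"
        assert out.p_value == pytest.approx(signed_rank_exact_oracle(d), abs=1e-12)


class TestFDR:
    def test_single_p_identity(self):
        np.testing.assert_allclose(fdr_adjust([0.05]), [0.05])

    def test_hand_stepup_case(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_adjusted_at_least_raw_and_permutation_equivariant(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        perm = rng.permutation(40)
        np.testing.assert_allclose(fdr_adjust(p[perm]), adj[perm], atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    def test_all_null_false_positive_control(self):
        rng = np.random.default_rng(7)
        fp = []
        for _ in range(20):
            p = rng.uniform(size=1000)
            fp.append(np.mean(fdr_adjust(p) < 0.05))
        assert np.mean(fp) <= 0.05


class TestPairwiseCounts:
    def test_identical_feature_values_give_zero_matrix(self):
        vals = {}
        for i, p in enumerate(["P1", "P2", "P3", "P4", "P5"]):
            for s in ("FBP", "IR20", "IR40", "IR50", "IR60", "IR80"):
                vals[(p, s, "original_glcm_A")] = float(i)
        t = make_table(vals)
        counts = pairwise_algorithm_counts(t)
        assert (counts.to_numpy() == 0).all()

    def test_symmetry_and_zero_diagonal(self):
        table, _ = simulate(get_preset("group3", seed=5))
        counts = pairwise_algorithm_counts(table)
        np.testing.assert_array_equal(counts.to_numpy(), counts.to_numpy().T)
        assert (np.diag(counts.to_numpy()) == 0).all()

    def test_single_shifted_feature_counted(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=12)
        vals = {}
        for i, p in enumerate([f"P{k}" for k in range(12)]):
            vals[(p, "FBP", "original_glcm_A")] = float(base[i])
            vals[(p, "IR60", "original_glcm_A")] = float(base[i] + 5.0)
        t = make_table(vals, design=ReconstructionDesign(
            ("FBP", "IR60"), "FBP", {"FBP": 0, "IR60": 60}))
        counts = pairwise_algorithm_counts(t)
        assert counts.loc["FBP", "IR60"] == 1

    def test_trend_counts_grow_with_blending_gap(self):
        table, _ = simulate(get_preset("group3", seed=6))
        counts = pairwise_algorithm_counts(table, image_type=None)
        row = counts.loc["FBP"]
        gaps = [row[s] for s in ("IR20", "IR40", "IR50", "IR60", "IR80")]
        assert all(b >= a for a, b in zip(gaps, gaps[1:]))


class TestBaseline:
    def _meta(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "scanner": rng.permutation(["scannerA"] * (n // 2) + ["scannerB"] * (n - n // 2)),
                "tube_voltage": rng.permutation(["100kVp"] * (n // 2) + ["120kVp"] * (n - n // 2)),
                "tumour_volume_cm3": rng.lognormal(3.5, 0.5, size=n),
                "gender": rng.choice(["M", "F"], size=n),
            },
            index=[f"P{i}" for i in range(n)],
        )

    def test_balanced_contingency_p_one(self):
        meta = pd.DataFrame(
            {
                "scanner": ["A"] * 10 + ["B"] * 10,
                "gender": (["M"] * 5 + ["F"] * 5) * 2,
            }
        )
        out = baseline_comparison(meta, "scanner")
        row = out[out["variable"] == "gender"].iloc[0]
        assert row["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_perfectly_separated_fisher_p(self):
        # 2x2 table [[5,0],[0,5]]: two-sided Fisher p = 2/C(10,5) = 2/252
        meta = pd.DataFrame(
            {"scanner": ["A"] * 5 + ["B"] * 5, "gender": ["M"] * 5 + ["F"] * 5}
        )
        out = baseline_comparison(meta, "scanner")
        row = out[out["variable"] == "gender"].iloc[0]
        assert row["test"] == "fisher"
        assert row["p_value"] == pytest.approx(2 / 252, abs=1e-12)

    def test_identical_continuous_variable_p_one(self):
        meta = pd.DataFrame(
            {"scanner": ["A"] * 6 + ["B"] * 6, "tumour_volume_cm3": [10.0] * 12}
        )
        out = baseline_comparison(meta, "scanner")
        row = out[out["variable"] == "tumour_volume_cm3"].iloc[0]
        assert row["p_value"] >= 0.98

    def test_missing_values_counted(self):
        meta = self._meta()
        meta.loc[meta.index[:3], "gender"] = None
        out = baseline_comparison(meta, "scanner")
        assert int(out.loc[out["variable"] == "gender", "n_missing"].iloc[0]) == 3

    def test_grouping_must_have_two_levels(self):
        meta = self._meta()
        meta["scanner"] = "onlyone"
        with pytest.raises(ValueError):
            baseline_comparison(meta, "scanner")
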