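"""Pearson matrices, ICV selection, the random-set null, and significance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibersync.fibration import FiberPartition
from fibersync.stats import (
    cross_fiber_corr,
    fiber_significance,
    functional_network,
    icv_select,
    mean_offdiag,
    pearson_matrix,
    random_null,
)


def frame(rows: dict, conditions=None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = conditions or [f"c{i}" for i in range(df.shape[1])]
    df.index.name = "gene"
    return df


class TestPearsonMatrix:
    def test_identical_profiles(self):
        expr = frame({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        C = pearson_matrix(expr, ["a", "b"])
        assert C.loc["a", "b"] == pytest.approx(1.0)

    def test_reversed_profiles(self):
        expr = frame({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        assert pearson_matrix(expr, ["a", "b"]).loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 1.5, sd_a = sqrt(1.25), sd_b = sqrt(2.25) (population moments)
        # => r = 1.5 / (1.1180 * 1.5) = 0.894427
        expr = frame({"a": [1, 2, 3, 4], "b": [1, 1, 4, 4]})
        C = pearson_matrix(expr, ["a", "b"])
        assert C.loc["a", "b"] == pytest.approx(0.8944, abs=1e-4)

    def test_zero_variance_gene_is_missing(self):
        expr = frame({"a": [1, 2, 3, 4], "b": [2, 2, 2, 2]})
        C = pearson_matrix(expr, ["a", "b"])
        assert math.isnan(C.loc["a", "b"])
        assert math.isnan(C.loc["b", "b"])
        assert C.loc["a", "a"] == 1.0

    def test_too_few_conditions_rejected(self):
        expr = frame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError):
            pearson_matrix(expr, ["a", "b"])

    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=30, derandomize=True)
    def test_affine_invariance_positive_scale(self, scale, shift):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(3, 12))
        expr = frame({g: base[i] for i, g in enumerate("abc")})
        shifted = expr * scale + shift
        C0 = pearson_matrix(expr, list("abc"))
        C1 = pearson_matrix(shifted, list("abc"))
        assert np.allclose(C0.to_numpy(), C1.to_numpy(), atol=1e-9)


class TestMeanOffdiag:
    def test_two_by_two(self):
        C = pd.DataFrame([[1.0, 0.98], [0.98, 1.0]])
        assert mean_offdiag(C) == pytest.approx(0.98)

    def test_constant_ones(self):
        C = pd.DataFrame(np.ones((3, 3)))
        assert mean_offdiag(C) == pytest.approx(1.0)

    def test_mixed_values(self):
        C = pd.DataFrame(np.eye(3))
        C.iloc[0, 1] = C.iloc[1, 0] = 0.2
        C.iloc[0, 2] = C.iloc[2, 0] = -0.2
        C.iloc[1, 2] = C.iloc[2, 1] = 0.6
        assert mean_offdiag(C) == pytest.approx(0.2)

    def test_missing_entries_excluded(self):
        C = pd.DataFrame([[1.0, np.nan, 0.5],
                          [np.nan, np.nan, np.nan],
                          [0.5, np.nan, 1.0]])
        assert mean_offdiag(C) == pytest.approx(0.5)

    def test_all_missing_is_an_error(self):
        C = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError):
            mean_offdiag(C)


class TestIcvSelect:
    def test_hand_computed_icv(self):
        expr = frame({"a": [1, 1], "b": [3, 3]}, conditions=["t1", "t2"])
        sel = icv_select(expr, ["a", "b"])
        # mu_t = 2, population sd_t = 1 -> ICV = 2
        assert sel.icv["t1"] == pytest.approx(2.0)

    def test_zero_dispersion_condition_selected(self):
        expr = frame({"a": [2, 1], "b": [2, 3]}, conditions=["t1", "t2"])
        sel = icv_select(expr, ["a", "b"])
        assert math.isinf(sel.icv["t1"])
        assert "t1" in sel.selected

    def test_threshold_and_zscore(self):
        # ICVs (2, 2, 2, 6): threshold 3, selected {t4},
        # sigma_ICV = sqrt(3), z_4 = 3/sqrt(3) = sqrt(3)
        expr = frame(
            {"a": [1, 1, 1, 2.5], "b": [3, 3, 3, 3.5]},
            conditions=["t1", "t2", "t3", "t4"],
        )
        sel = icv_select(expr, ["a", "b"])
        assert list(sel.icv) == pytest.approx([2, 2, 2, 6])
        assert sel.mu_icv == pytest.approx(3.0)
        assert sel.selected == ("t4",)
        assert sel.z["t4"] == pytest.approx(1.7321, abs=1e-4)

    def test_single_gene_rejected(self):
        expr = frame({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            icv_select(expr, ["a"])

    def test_scale_invariant_not_shift_invariant(self):
        rng = np.random.default_rng(1)
        expr = frame({g: rng.normal(2, 1, 20) for g in "abcd"})
        base = icv_select(expr, list("abcd"))
        scaled = icv_select(expr * 7.0, list("abcd"))
        assert base.selected == scaled.selected
        shifted = icv_select(expr + 5.0, list("abcd"))
        assert base.selected != shifted.selected


class TestRandomNull:
    def noise(self, n=40, T=150, seed=0):
        rng = np.random.default_rng(seed)
        return frame({f"g{i}": rng.normal(size=T) for i in range(n)})

    def test_noise_null_centred_at_zero(self):
        mu, sigma = random_null(self.noise(), 2, 3000, "none", 1)
        assert abs(mu) < 3 * sigma / math.sqrt(3000) + 1e-3

    def test_deterministic_given_seed(self):
        expr = self.noise()
        assert random_null(expr, 3, 500, "none", 9) == random_null(
            expr, 3, 500, "none", 9
        )

    def test_icv_filtering_inflates_null_on_compendium_like_data(self, study):
        """Condition selection induces correlation: the size-2 ICV null mean
        sits far above the unfiltered null mean (it approaches 1 as the set
        size approaches 2)."""
        expr = study.expr
        mu_none, _ = random_null(expr, 2, 400, "none", 2)
        mu_icv, _ = random_null(expr, 2, 400, "icv", 2)
        assert mu_icv > mu_none + 0.2

    def test_size_bounds(self):
        with pytest.raises(ValueError):
            random_null(self.noise(5), 6, 10, "none", 0)
        with pytest.raises(ValueError):
            random_null(self.noise(), 1, 10, "none", 0)

    def test_null_mean_stable_under_sample_size_reduction(self):
        """Shrinking the null from 100,000 to 10,000 samples moves the mean
        by less than 3 standard errors of the smaller sample."""
        expr = self.noise()
        mu_big, sigma = random_null(expr, 2, 100_000, "none", 7)
        mu_small, _ = random_null(expr, 2, 10_000, "none", 8)
        assert abs(mu_big - mu_small) < 3 * sigma / math.sqrt(10_000)

    def test_sampling_sd_scales_like_sigma_over_sqrt_m(self):
        """Means of m-subsamples of the null have sd close to sigma/sqrt(m)."""
        _, sigma, vals = random_null(
            self.noise(), 2, 4096, "none", 3, return_samples=True
        )
        rng = np.random.default_rng(4)
        for m in (4, 16, 64):
            means = rng.choice(vals, size=(600, m), replace=True).mean(axis=1)
            assert means.std(ddof=0) == pytest.approx(
                sigma / math.sqrt(m), rel=0.10
            )


class TestFiberSignificance:
    def test_null_centre_gives_p_half(self):
        # a "fiber" drawn from the same noise as the null: Z ~ 0, p ~ 0.5
        rng = np.random.default_rng(5)
        expr = frame({f"g{i}": rng.normal(size=300) for i in range(30)})
        partition = FiberPartition.from_colors(
            {f"g{i}": (0 if i < 2 else i) for i in range(30)}
        )
        res = fiber_significance(partition, expr, "none", 2000, seed=1)
        row = res.table.iloc[0]
        assert abs(row["Z"]) < 3
        assert 0.01 < row["p"] < 0.99
        assert row["m"] == 1 and row["size"] == 2

    def test_missing_members_drop_fiber(self):
        rng = np.random.default_rng(6)
        expr = frame({f"g{i}": rng.normal(size=50) for i in range(10)})
        partition = FiberPartition.from_colors(
            {**{f"g{i}": 0 for i in range(2)}, "absent": 1, "g5": 1}
        )
        res = fiber_significance(partition, expr, "none", 200, seed=1)
        assert res.meta["fibers_dropped"] == 1
        assert len(res.per_fiber) == 1
        assert set(res.per_fiber["fiber_id"]) == {partition.fiber_of("g0")}

    def test_empty_size_range_is_empty_table(self):
        rng = np.random.default_rng(7)
        expr = frame({f"g{i}": rng.normal(size=50) for i in range(6)})
        partition = FiberPartition.from_colors({f"g{i}": 0 for i in range(6)})
        res = fiber_significance(partition, expr, "none", 100, seed=0,
                                 size_range=(2, 4))
        assert res.table.empty


class TestCrossFiberCorr:
    def test_same_fiber_idempotent(self):
        rng = np.random.default_rng(8)
        expr = frame({g: rng.normal(2, 1, 80) for g in "abcd"})
        sel = icv_select(expr, ["a", "b"])
        C = cross_fiber_corr(expr, ["a", "b"], sel, ["a", "b"], sel)
        ref = pearson_matrix(expr, ["a", "b"], list(sel.selected))
        assert np.allclose(C.to_numpy(), ref.to_numpy(), equal_nan=True)

    def test_independent_fibers_uncorrelated(self):
        rng = np.random.default_rng(9)
        expr = frame({g: rng.normal(size=400) for g in "abcd"})
        C = cross_fiber_corr(expr, ["a", "b"], None, ["c", "d"], None)
        off = [abs(C.loc[i, j]) for i in "ab" for j in "cd"]
        assert max(off) < 0.2

    def test_shared_drive_couples_fibers(self):
        rng = np.random.default_rng(10)
        drive = rng.normal(size=200)
        expr = frame(
            {g: drive + rng.normal(0, 0.3, 200) for g in "abcd"}
        )
        sa = icv_select(expr, ["a", "b"])
        sb = icv_select(expr, ["c", "d"])
        C = cross_fiber_corr(expr, ["a", "b"], sa, ["c", "d"], sb)
        assert C.loc["a", "c"] > 0.5

    def test_mismatched_modes_rejected(self):
        expr = frame({g: np.arange(8.0) for g in "abcd"})
        with pytest.raises(ValueError):
            cross_fiber_corr(expr, ["a"], None, ["b"], icv_select(expr, ["a", "b"]))


class TestFunctionalNetwork:
    def test_below_threshold_empty(self):
        C = pd.DataFrame(np.full((3, 3), 0.5), index=list("abc"), columns=list("abc"))
        assert functional_network(C, 0.6) == []

    def test_strong_pair_is_an_edge(self):
        C = pd.DataFrame([[1.0, 0.98], [0.98, 1.0]], index=["rrsH", "rrsG"],
                         columns=["rrsH", "rrsG"])
        assert functional_network(C) == [("rrsH", "rrsG", 0.98)]

    def test_boundary_is_strict(self):
        C = pd.DataFrame([[1.0, 0.6], [0.6, 1.0]], index=list("ab"),
                         columns=list("ab"))
        assert functional_network(C, 0.6) == []
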