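"""The DG vs CA log-ratio axis: delta, Welch t, permutation, folds, FPKM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from endoatlas.axis import (
    analyze_axis,
    compute_delta,
    floor_fpkm,
    fold_difference,
    fpkm_axis,
    group_fold,
    permutation_test,
    welch_t,
)
from endoatlas.expression import normalize_profiles
from endoatlas.regions import ConfigurationError, UndefinedTestError
from endoatlas.synthetic import SyntheticConfig, generate_all


def _norm_table(rows):
    recs = [{"gene": f"g{i}", "CA1": r[0], "CA2": r[1], "CA3": r[2], "DG": r[3]}
            for i, r in enumerate(rows)]
    return pd.DataFrame(recs)


def _delta_df(a_vals, b_vals):
    return pd.DataFrame({
        "gene": [f"g{i}" for i in range(len(a_vals) + len(b_vals))],
        "delta": list(a_vals) + list(b_vals),
        "group": ["A"] * len(a_vals) + ["B"] * len(b_vals),
    })


class TestComputeDelta:
    def test_equal_dg_and_ca_gives_zero(self):
        d = compute_delta(_norm_table([(50, 50, 50, 50)]))
        assert d.loc[0, "delta"] == 0.0

    def test_powers_of_ten(self):
        # DG 99, CA all 9, offset 1: log10(100) - log10(10) = 1
        d = compute_delta(_norm_table([(9, 9, 9, 99)]), offset=1)
        assert d.loc[0, "delta"] == pytest.approx(1.0)

    def test_all_zero_row_with_offset_two(self):
        d = compute_delta(_norm_table([(0, 0, 0, 0)]), offset=2)
        assert d.loc[0, "delta"] == 0.0

    def test_invalid_offset_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_delta(_norm_table([(1, 1, 1, 1)]), offset=3)

    def test_missing_subfield_excluded_and_counted(self):
        t = _norm_table([(10, 10, 10, 50), (10, np.nan, 10, 50)])
        d = compute_delta(t)
        assert len(d) == 1 and d.attrs["n_excluded"] == 1

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0, 100), st.floats(0, 100))
    def test_antisymmetry(self, dg, ca):
        """Swapping DG with the CA mean negates delta."""
        d1 = compute_delta(_norm_table([(ca, ca, ca, dg)]))
        d2 = compute_delta(_norm_table([(dg, dg, dg, ca)]))
        assert d1.loc[0, "delta"] == pytest.approx(-d2.loc[0, "delta"], abs=1e-12)

    def test_limit_of_vanishing_offset_is_plain_log_ratio(self):
        # with strictly positive values, offset-free delta = log10(DG/meanCA);
        # offsets 1 and 2 bracket it ever closer as values grow
        big = _norm_table([(1000.0, 1000.0, 1000.0, 10000.0)])
        d = compute_delta(big, offset=1)
        assert d.loc[0, "delta"] == pytest.approx(1.0, abs=1e-3)


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_welch_equal_variances(self):
        res = welch_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.224745, abs=1e-6)
        assert res.df == pytest.approx(4.0)

    def test_too_small_group_undefined(self):
        with pytest.raises(UndefinedTestError):
            welch_t([1.0], [1.0, 2.0])


class TestPermutation:
    def test_degenerate_null_gives_p_one(self):
        res = permutation_test(_delta_df([1.0, 1.0], [1.0, 1.0, 1.0]))
        assert res.p == 1.0

    def test_exhaustive_enumeration_small_fixture(self):
        """A={1,2}, B={10,11}: 6 label assignments, exactly 2 reach
        |diff| >= 9, so p = 2/6 exactly."""
        res = permutation_test(_delta_df([1.0, 2.0], [10.0, 11.0]))
        assert res.exhaustive
        assert res.p == pytest.approx(2 / 6)

    def test_monte_carlo_agrees_with_exhaustive(self):
        """On every small fixture the sampled p lands within 0.01 of the
        exact enumeration p."""
        rng = np.random.default_rng(12)
        for n_total in (6, 8, 10, 12):
            na = n_total // 2
            vals = rng.normal(0.4, 1.0, n_total)
            df = _delta_df(vals[:na] + 0.8, vals[na:])
            exact = permutation_test(df)
            assert exact.exhaustive
            # force the Monte-Carlo path by lifting the exhaustive limit
            import endoatlas.axis as axis_mod
            old = axis_mod.EXHAUSTIVE_LIMIT
            axis_mod.EXHAUSTIVE_LIMIT = 0
            try:
                mc = permutation_test(df, reps=10_000, seed=99)
            finally:
                axis_mod.EXHAUSTIVE_LIMIT = old
            assert abs(mc.p - exact.p) < 0.01

    def test_seed_reproducible(self):
        df = _delta_df(np.arange(10.0), np.arange(10.0) + 0.5)
        p1 = permutation_test(df, reps=2000, seed=7).p
        p2 = permutation_test(df, reps=2000, seed=7).p
        assert p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            permutation_test(_delta_df([1.0, 2.0], []))


class TestFolds:
    def test_equal_group_means_give_fold_one(self):
        assert fold_difference(_delta_df([0.5, -0.5], [0.3, -0.3])) == pytest.approx(1.0)

    def test_unit_log10_difference_gives_ten(self):
        assert fold_difference(_delta_df([1.0, 1.0], [0.0, 0.0])) == pytest.approx(10.0)

    def test_group_fold_orientation(self):
        df = _delta_df([np.log10(8.0)] * 3, [-np.log10(5.0)] * 3)
        assert group_fold(df, "A") == pytest.approx(8.0)
        assert group_fold(df, "B") == pytest.approx(5.0)

    def test_invariant_to_log_base(self):
        df2 = _delta_df([1.0, 2.0], [0.5, 0.1])
        f10 = fold_difference(df2, log_base=10)
        # same deltas re-expressed in natural log units
        dfe = df2.copy()
        dfe["delta"] *= np.log(10)
        fe = fold_difference(dfe, log_base=np.e)
        assert f10 == pytest.approx(fe)


class TestFpkm:
    def test_floor_is_inclusive_at_four(self):
        t = pd.DataFrame({"gene": ["a", "b"], "CA1": [3.9, 4.0], "CA2": [5, 5],
                          "CA3": [5, 5], "DG": [10, 10]})
        out = floor_fpkm(t)
        assert out.loc[0, "CA1"] == 0.0   # 3.9 < 4: undetected
        assert out.loc[1, "CA1"] == 4.0   # exactly 4: retained

    def test_fpkm_axis_sign_matches_intensity_axis(self):
        """The RNA-seq cross-validation reproduces the direction of the
        intensity-based group difference on coupled synthetic data."""
        data = generate_all(SyntheticConfig(seed=21))
        norm = normalize_profiles(data["profiles"], regions=["CA1", "CA2", "CA3", "DG"])
        res_int = analyze_axis(norm, data["groups"], reps=2000, seed=1)
        res_fpkm = fpkm_axis(data["fpkm"], data["groups"], reps=2000, seed=1)
        assert np.sign(res_int.permutation.observed) == np.sign(res_fpkm.permutation.observed)
        assert res_fpkm.permutation.p < 0.01


class TestOffsetStability:
    def test_group_conclusions_stable_across_offsets(self, default_data):
        """Offsets 1 and 2 yield the same group-difference sign and the
        same permutation significance on synthetic defaults."""
        norm = normalize_profiles(default_data["profiles"],
                                  regions=["CA1", "CA2", "CA3", "DG"])
        res = {off: analyze_axis(norm, default_data["groups"], offset=off,
                                 reps=5000, seed=4) for off in (1, 2)}
        assert np.sign(res[1].permutation.observed) == np.sign(res[2].permutation.observed)
        assert (res[1].permutation.p < 0.05) == (res[2].permutation.p < 0.05)
        assert np.sign(res[1].welch.statistic) == np.sign(res[2].welch.statistic)
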