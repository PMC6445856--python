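"""t-tests, correlations, BH step-up and the association battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import slidesample as ss
from slidesample.profiling import CELL_TYPES


def _welch_oracle(g0, g1):
    """Textbook Welch t statistic with Welch-Satterthwaite df."""
    g0, g1 = np.asarray(g0, float), np.asarray(g1, float)
    v0, v1 = g0.var(ddof=1) / len(g0), g1.var(ddof=1) / len(g1)
    t = (g0.mean() - g1.mean()) / np.sqrt(v0 + v1)
    df = (v0 + v1) ** 2 / (v0**2 / (len(g0) - 1) + v1**2 / (len(g1) - 1))
    return t, df


def _bh_oracle(p, alpha):
    """Brute-force step-up: check every rank threshold explicitly."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        # threshold written as alpha*(k/m) so the k = m rung is exactly alpha
        if p[order[k - 1]] <= alpha * (k / m):
            k_star = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_star]] = True
    return flags


class TestTwoSampleTTest:
    def test_identical_groups(self):
        res = ss.two_sample_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0 and res.p == pytest.approx(1.0)

    def test_separated_groups(self):
        res = ss.two_sample_t_test([1, 2, 3], [101, 102, 103])
        assert res.p < 1e-6

    def test_matches_closed_form(self, rng):
        g0, g1 = [1.1, 2.3, 3.1], [2.0, 2.5, 4.0, 5.1]
        res = ss.two_sample_t_test(g0, g1)
        t_oracle, df = _welch_oracle(g0, g1)
        assert res.t == pytest.approx(t_oracle, abs=1e-10)
        from scipy import stats

        p_oracle = 2 * stats.t.sf(abs(t_oracle), df)
        assert res.p == pytest.approx(p_oracle, abs=1e-10)
        assert res.mean0 == pytest.approx(np.mean(g0))

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            ss.two_sample_t_test([1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            ss.two_sample_t_test([2, 2, 2], [3, 3, 3])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert ss.pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert ss.pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.2, 1.9, 3.1, 5.0, 4.7])
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert ss.pearson_correlation(x, y)[0] == pytest.approx(r_oracle, abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            ss.pearson_correlation([1, 1, 1], [1, 2, 3])


class TestCellCorrelationMatrix:
    def test_duplicated_features_fully_correlated(self):
        col = np.random.default_rng(0).uniform(0, 1, 50)
        prof = np.column_stack([col, col, col, col])
        corr = ss.cell_correlation_matrix(prof)
        assert np.allclose(corr.to_numpy(), 1.0)

    def test_independent_features_uncorrelated(self, rng):
        prof = rng.standard_normal((10_000, 4))
        corr = ss.cell_correlation_matrix(prof).to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_symmetric_unit_diagonal(self, rng):
        corr = ss.cell_correlation_matrix(rng.uniform(0, 5, (30, 4)))
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_constant_feature_raises(self, rng):
        prof = rng.uniform(0, 1, (30, 4))
        prof[:, 2] = 3.0
        with pytest.raises(ValueError):
            ss.cell_correlation_matrix(prof)


class TestBHAdjust:
    def test_single_small_p_flagged(self):
        assert ss.bh_adjust([0.03], alpha=0.05).tolist() == [True]

    def test_four_equal_small_ps_all_flagged(self):
        # p_(4) = 0.01 <= 4 * 0.05 / 4
        assert ss.bh_adjust([0.01] * 4, alpha=0.05).all()

    def test_step_up_by_hand(self):
        # 0.04 > 0.025 and 0.9 > 0.05: nothing flagged
        assert not ss.bh_adjust([0.04, 0.9], alpha=0.05).any()

    def test_empty_input(self):
        assert ss.bh_adjust([], alpha=0.05).size == 0

    def test_invalid_ps_raise(self):
        with pytest.raises(ValueError):
            ss.bh_adjust([0.5, 1.2])

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20),
        st.floats(0.01, 0.2),
    )
    def test_matches_brute_force_oracle(self, ps, alpha):
        assert np.array_equal(ss.bh_adjust(ps, alpha), _bh_oracle(ps, alpha))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=15))
    def test_lowering_a_p_never_unflags_smaller_ps(self, ps):
        flags = ss.bh_adjust(ps, 0.05)
        lowered = list(ps)
        lowered[-1] = lowered[-1] / 2
        new_flags = ss.bh_adjust(lowered, 0.05)
        for i in range(len(ps) - 1):
            if flags[i] and ps[i] <= min(ps[-1], lowered[-1]):
                assert new_flags[i]


def _profile_frame(values, ids=None):
    ids = ids or [f"S{i}" for i in range(len(values))]
    return pd.DataFrame(values, index=ids, columns=list(CELL_TYPES))


class TestAssociationBattery:
    def test_identical_groups_not_flagged(self):
        vals = np.tile([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0],
                        [3.0, 4.0, 5.0, 6.0]], (2, 1))
        profiles = _profile_frame(vals)
        clinical = pd.DataFrame(
            {"grp": ["a", "a", "a", "b", "b", "b"]}, index=profiles.index
        )
        report = ss.association_battery(profiles, clinical, alpha=0.05)
        assert len(report) == 4
        assert np.allclose(report["p_value"], 1.0)
        assert not report["significant"].any()

    def test_strong_effect_flagged(self, rng):
        base = rng.uniform(1, 2, size=(40, 4))
        base[20:, 2] += 50  # huge fibroblast shift in group b
        profiles = _profile_frame(base)
        clinical = pd.DataFrame({"grp": ["a"] * 20 + ["b"] * 20}, index=profiles.index)
        report = ss.association_battery(profiles, clinical)
        row = report[report.cell_type == "fibroblast"].iloc[0]
        assert row.significant and row.mean1 > row.mean0

    def test_continuous_variable_uses_pearson(self, rng):
        profiles = _profile_frame(rng.uniform(0, 1, (30, 4)))
        clinical = pd.DataFrame(
            {"age": profiles["epithelial"] * 10 + 40}, index=profiles.index
        )
        report = ss.association_battery(profiles, clinical)
        epi = report[(report.variable == "age") & (report.cell_type == "epithelial")]
        assert epi.iloc[0].kind == "pearson"
        assert epi.iloc[0].statistic == pytest.approx(1.0)

    def test_variable_filtering(self, rng):
        profiles = _profile_frame(rng.uniform(0, 1, (20, 4)))
        clinical = pd.DataFrame(
            {
                "mostly_missing": [None] * 15 + ["x", "y", "x", "y", "x"],
                "constant": ["c"] * 20,
                "ok": ["a", "b"] * 10,
            },
            index=profiles.index,
        )
        report = ss.association_battery(profiles, clinical)
        assert set(report["variable"]) == {"ok"}

    def test_slide_order_invariance(self, rng):
        profiles = _profile_frame(rng.uniform(0, 3, (24, 4)))
        clinical = pd.DataFrame({"grp": ["a", "b"] * 12}, index=profiles.index)
        report1 = ss.association_battery(profiles, clinical)
        perm = rng.permutation(24)
        report2 = ss.association_battery(
            profiles.iloc[perm], clinical.iloc[rng.permutation(24)]
        )
        pd.testing.assert_frame_equal(report1, report2)

    def test_family_is_all_executed_tests(self, rng):
        profiles = _profile_frame(rng.uniform(0, 1, (30, 4)))
        clinical = pd.DataFrame(
            {"g1": ["a", "b"] * 15, "g2": ["x"] * 15 + ["y"] * 15},
            index=profiles.index,
        )
        report = ss.association_battery(profiles, clinical)
        assert len(report) == 8  # 2 variables x 4 types, one BH family
        assert np.array_equal(
            report["significant"].to_numpy(),
            ss.bh_adjust(report["p_value"].to_numpy(), 0.05),
        )
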