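import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, strategies as st

from aquamyo.io import load_printed_results
from aquamyo.stats import (
    cv_percent,
    environment_report,
    icc,
    min_aquatic_increase,
    oneway_f,
    two_sample_t,
)


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], equal_var=True)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_hand_computation(self):
        # pooled variance 1, means 2 vs 5: t = -3/sqrt(2/3)
        res = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], equal_var=True)
        assert res.t_statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-4)
        assert res.df == pytest.approx(4)

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(10), 1 + rng.standard_normal(12)
        fwd, rev = two_sample_t(a, b), two_sample_t(b, a)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestOnewayF:
    def test_degenerate_identical_groups(self):
        with pytest.raises(ValueError):
            oneway_f([[2.0, 2.0], [2.0, 2.0]])

    def test_zero_within_variance_unequal_means(self):
        res = oneway_f([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(res.F_statistic)
        assert res.p_value == 0.0

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.standard_normal(30), rng.standard_normal(30) + 0.5
        t = two_sample_t(a, b, equal_var=True)
        f = oneway_f([a, b])
        assert f.F_statistic == pytest.approx(t.t_statistic**2, abs=1e-9)
        assert (f.df1, f.df2) == (1, 58)

    def test_three_group_sum_of_squares_decomposition(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [5.0, 5.0, 8.0]]
        flat = [v for g in groups for v in g]
        grand = np.mean(flat)
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum((v - np.mean(g)) ** 2 for g in groups for v in g)
        expected = (ssb / 2) / (ssw / 6)
        res = oneway_f(groups)
        assert res.F_statistic == pytest.approx(expected, rel=1e-12)
        assert (res.df1, res.df2) == (2, 6)


class TestIcc:
    def test_perfect_agreement(self):
        table = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [9.0, 9.0]])
        for form in ("1,1", "C,1", "A,1"):
            assert icc(table, form=form) == pytest.approx(1.0)

    def test_small_table_matches_mean_square_oracle(self):
        table = np.array([[1.0, 2.0], [3.0, 2.5], [6.0, 7.0], [9.0, 8.0]])
        n, k = table.shape
        grand = table.mean()
        msr = k * np.sum((table.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((table.mean(axis=0) - grand) ** 2) / (k - 1)
        sse = np.sum((table - grand) ** 2) - msr * (n - 1) - msc * (k - 1)
        mse = sse / ((n - 1) * (k - 1))
        expected_c1 = (msr - mse) / (msr + (k - 1) * mse)
        expected_a1 = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        assert icc(table, form="C,1") == pytest.approx(expected_c1, rel=1e-12)
        assert icc(table, form="A,1") == pytest.approx(expected_a1, rel=1e-12)

    def test_matches_pingouin_reference(self, rng):
        table = rng.standard_normal((8, 3)) + rng.standard_normal((8, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "rater": np.tile(np.arange(3), 8),
                "score": table.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")["ICC"]
        assert icc(table, form="1,1") == pytest.approx(ref["ICC(1,1)"], abs=1e-9)
        assert icc(table, form="A,1") == pytest.approx(ref["ICC(A,1)"], abs=1e-9)
        assert icc(table, form="C,1") == pytest.approx(ref["ICC(C,1)"], abs=1e-9)

    def test_missing_cells_rejected(self):
        table = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            icc(table)

    def test_variance_component_recovery(self):
        # subjects N(0, 9), residual N(0, 1): analytic ICC = 0.9
        rng = np.random.default_rng(42)
        n = 200
        subj = 3.0 * rng.standard_normal((n, 1))
        table = subj + rng.standard_normal((n, 2))
        assert icc(table, form="C,1") == pytest.approx(0.9, abs=0.05)


class TestCvPercent:
    def test_hand_computation(self):
        assert cv_percent([9.0, 11.0]) == pytest.approx(np.sqrt(2) / 10 * 100, rel=1e-9)

    def test_identical_values(self):
        assert cv_percent([5.0, 5.0, 5.0]) == 0.0

    @given(st.floats(min_value=0.01, max_value=1000.0))
    def test_scale_invariance(self, c):
        vals = np.array([3.0, 4.0, 5.5, 4.2])
        assert cv_percent(c * vals) == pytest.approx(cv_percent(vals), rel=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent([-1.0, -2.0])


def toy_feature_table(noise=0.0, offset=0.4, n_subjects=6, seed=0):
    """Hand-built long table: per-subject level + environment offset, set noise.

    The additive environment effect keeps the noiseless two-way table free
    of subject × environment interaction, so consistency ICC is exactly 1.
    """
    rng = np.random.default_rng(seed)
    levels = 2.0 + 0.3 * rng.standard_normal(n_subjects)
    rows = []
    for s in range(n_subjects):
        for env, off in (("land", 0.0), ("aquatic", offset)):
            for reps in (3, 6):
                for st_ in (1, 2, 3):
                    eps = 1.0 + noise * rng.standard_normal()
                    rows.append(
                        dict(subject_id=f"S{s}", protocol="BC", environment=env,
                             reps=reps, arm="right", set=st_, feature="RMS",
                             value=(levels[s] + off) * eps)
                    )
    return pd.DataFrame(rows)


class TestEnvironmentReport:
    def test_noiseless_table_gives_perfect_reliability(self):
        rep = environment_report(toy_feature_table(noise=0.0))
        assert rep.loc[0, "icc"] == pytest.approx(1.0)
        assert rep.loc[0, "cv_percent"] == pytest.approx(0.0, abs=1e-9)

    def test_aquatic_mean_exceeds_land(self):
        rep = environment_report(toy_feature_table(noise=0.02))
        assert (rep["aquatic_mean"] > rep["land_mean"]).all()

    def test_subject_relabeling_invariance(self):
        table = toy_feature_table(noise=0.05)
        relabeled = table.copy()
        mapping = {f"S{i}": f"Q{9 - i}" for i in range(6)}
        relabeled["subject_id"] = relabeled["subject_id"].map(mapping)
        a = environment_report(table)
        b = environment_report(relabeled)
        for col in ("t_statistic", "p_value", "F_statistic", "icc", "cv_percent"):
            assert a.loc[0, col] == pytest.approx(b.loc[0, col], rel=1e-9)

    def test_single_environment_rejected(self):
        table = toy_feature_table()
        with pytest.raises(ValueError):
            environment_report(table[table.environment == "land"])


class TestMinAquaticIncrease:
    def test_published_example_cell(self):
        printed = load_printed_results()
        m, _ = printed.lookup("IEMG", "land", "BC", 3, "left")
        a, _ = printed.lookup("IEMG", "aquatic", "BC", 3, "left")
        assert 100 * (a - m) / m == pytest.approx(8.311, abs=0.001)

    def test_identical_table_gives_zero(self):
        printed = load_printed_results()
        df = printed.df.copy()
        land = df[df.environment == "land"].copy()
        land["environment"] = "aquatic"
        null = pd.concat([df[df.environment == "land"], land])
        assert min_aquatic_increase(null) == pytest.approx(0.0)

    def test_full_table_minimum_at_least_six_percent(self):
        assert min_aquatic_increase(load_printed_results()) >= 6.0
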