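import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from arraybsa.errors import DegenerateDataError, InsufficientDataError
from arraybsa.simulate import exact_moment_sample
from arraybsa.stats import (
    GroupStats,
    fisher_ratio,
    group_stats,
    independent_t_test,
    levene_test,
)

finite_values = st.lists(
    st.floats(-1e3, 1e3, allow_nan=False), min_size=3, max_size=20
).filter(lambda v: np.std(v, ddof=1) > 1e-6)


class TestGroupStats:
    def test_simple(self):
        g = group_stats([1, 2, 3])
        assert (g.n, g.mean, g.variance, g.sd) == (3, 2.0, 1.0, 1.0)

    def test_constant_vector_has_zero_variance(self):
        assert group_stats([5, 5, 5, 5]).variance == 0.0

    def test_exact_moment_fixture_recovers_targets(self):
        vals = exact_moment_sample(12, 743.53, 252.08, seed=1)
        g = group_stats(vals)
        assert g.mean == pytest.approx(743.53, abs=1e-9)
        assert g.sd == pytest.approx(252.08, abs=1e-9)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            group_stats([1.0])


class TestFisherRatio:
    def test_equal_means_zero(self):
        g = GroupStats("a", 5, 3.0, 2.0)
        assert fisher_ratio(g, GroupStats("b", 5, 3.0, 4.0)) == 0.0

    def test_hand_value(self):
        assert fisher_ratio(
            GroupStats("a", 5, 3.0, 1.0), GroupStats("b", 5, 1.0, 1.0)
        ) == pytest.approx(2.0)

    def test_reference_marker_value(self):
        # strongest DN1-SD marker of the reference study:
        # (743.53-259.98)^2 / (252.08^2 + 148.78^2)
        g1 = GroupStats("DN1", 12, 743.53, 252.08**2)
        g2 = GroupStats("SD", 12, 259.98, 148.78**2)
        assert fisher_ratio(g1, g2) == pytest.approx(2.729, abs=1e-3)

    def test_degenerate_variances(self):
        with pytest.raises(DegenerateDataError):
            fisher_ratio(GroupStats("a", 3, 1.0, 0.0), GroupStats("b", 3, 2.0, 0.0))
        assert fisher_ratio(
            GroupStats("a", 3, 1.0, 0.0), GroupStats("b", 3, 1.0, 0.0)
        ) == 0.0

    @given(finite_values, finite_values)
    def test_symmetric_in_group_order(self, a, b):
        g1, g2 = group_stats(a), group_stats(b)
        assert fisher_ratio(g1, g2) == pytest.approx(fisher_ratio(g2, g1))


class TestLevene:
    def test_identical_lists_give_p_one(self):
        assert levene_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_detects_25x_variance(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 5, 50)
        assert levene_test(a, b) < 0.01

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert levene_test(a, b) == pytest.approx(levene_test(b, a))


class TestIndependentT:
    def test_identical_groups(self):
        r = independent_t_test([1, 2, 3, 4], [1, 2, 3, 4], variant="pooled")
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_pooled_reference_row(self):
        dn = exact_moment_sample(12, 743.53, 252.08, seed=1)
        sd = exact_moment_sample(12, 259.98, 148.78, seed=2)
        r = independent_t_test(dn, sd, variant="pooled")
        assert r.t == pytest.approx(5.723, abs=1e-3)
        assert r.df == 22
        assert r.p < 0.01 and r.significance == "**"

    def test_welch_reference_row(self):
        dn = exact_moment_sample(12, 85.71, 48.94, seed=3)
        sd = exact_moment_sample(12, 232.53, 172.45, seed=4)
        r = independent_t_test(dn, sd, variant="welch")
        assert r.t == pytest.approx(-2.837, abs=1e-3)
        assert r.df_rounded == pytest.approx(12.8)

    def test_zero_se_unequal_means_is_infinite_sentinel(self):
        r = independent_t_test([1, 1, 1], [2, 2, 2], variant="pooled")
        assert math.isinf(r.t) and r.t < 0 and r.p == 0.0

    @given(finite_values, finite_values)
    def test_antisymmetric_and_welch_df_bounds(self, a, b):
        r = independent_t_test(a, b, variant="welch")
        s = independent_t_test(b, a, variant="welch")
        assert r.t == pytest.approx(-s.t, rel=1e-9, abs=1e-12)
        n1, n2 = len(a), len(b)
        assert min(n1, n2) - 1 <= r.df + 1e-9
        assert r.df <= n1 + n2 - 2 + 1e-9

    def test_auto_resolves_by_levene(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 10, 30)
        assert independent_t_test(a, b).variant == "welch"
        c = rng.normal(0, 1, 30)
        assert independent_t_test(a, c).variant == "pooled"
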