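"""Rank tests and percent-difference statistics between protein groups."""

import numpy as np
import pytest
from scipy import stats

from stoichioprot.compare import compare_groups, mann_whitney_u, percent_difference


class TestMannWhitney:
    def test_fully_separated_toy_example_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 of the C(6,3) assignments

    def test_identical_multisets_near_null_p(self):
        a = [1.0, 2.0, 2.0, 3.0] * 5
        _, p = mann_whitney_u(a, list(a), method="approx")
        assert p >= 0.99

    def test_swap_symmetry(self):
        rng = np.random.default_rng(8)
        for n_a, n_b in ((5, 7), (20, 30)):
            a, b = rng.normal(size=n_a), rng.normal(0.3, 1, size=n_b)
            u1, p1 = mann_whitney_u(a, b)
            u2, p2 = mann_whitney_u(b, a)
            assert u1 + u2 == pytest.approx(n_a * n_b)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_exact_path_matches_scipy_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.normal(size=int(rng.integers(2, 7)))
            b = rng.normal(size=int(rng.integers(2, 7)))
            u, p = mann_whitney_u(a, b, method="exact")
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_path_handles_ties_as_permutation_null(self):
        # two-point pooled distribution: normal theory would be meaningless
        _, p = mann_whitney_u([1.0, 1.0], [1.0, 4.0], method="exact")
        assert p == pytest.approx(1.0)

    def test_approx_close_to_exact_on_small_samples(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n_a = int(rng.integers(2, 9))
            n_b = int(rng.integers(max(2, 6 - n_a), 13 - n_a))
            a, b = rng.normal(size=n_a), rng.normal(size=n_b)
            _, pe = mann_whitney_u(a, b, method="exact")
            _, pa = mann_whitney_u(a, b, method="approx")
            assert abs(pe - pa) <= 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_one_sided_alternatives_order(self):
        a, b = [5, 6, 7, 8], [1, 2, 3, 4]
        _, p_greater = mann_whitney_u(a, b, alternative="greater")
        _, p_less = mann_whitney_u(a, b, alternative="less")
        assert p_greater < 0.05 < p_less


class TestCarbonControlCalibration:
    def test_random_group_carbon_p_values_roughly_uniform(self, small_study):
        from stoichioprot.elements import element_content_many

        contents = element_content_many(
            [r.sequence for r in small_study.records], "C"
        )
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(200):
            idx = rng.permutation(len(contents))
            ps.append(mann_whitney_u(contents[idx[:30]], contents[idx[30:60]])[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPercentDifference:
    def test_reported_group_means_give_3_2_percent(self):
        assert round(percent_difference(0.481, 0.466), 1) == 3.2

    @pytest.mark.parametrize("a,b,expected", [(1.0, 1.0, 0.0), (2.0, 1.0, 100.0)])
    def test_simple_values(self, a, b, expected):
        assert percent_difference(a, b) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


class TestCompareGroups:
    def contents(self, mapping):
        return {pid: {"O": o, "C": c} for pid, (o, c) in mapping.items()}

    def test_identical_groups_null(self):
        contents = self.contents(
            {f"A{i}": (0.5, 3.0) for i in range(5)}
            | {f"B{i}": (0.5, 3.0) for i in range(5)}
        )
        res = compare_groups(
            contents, {f"A{i}" for i in range(5)}, {f"B{i}" for i in range(5)}, "O"
        )
        assert res[0].percent_difference == pytest.approx(0.0)
        assert res[0].p_value >= 0.99

    def test_separated_hand_computed_contents(self):
        # group_a: all "DD" (O=2); group_b: all "GG" (O=0)
        contents = {f"D{i}": {"O": 2.0, "C": 2.0} for i in range(4)}
        contents |= {f"G{i}": {"O": 0.0, "C": 0.0} for i in range(4)}
        res = compare_groups(
            contents, {f"D{i}" for i in range(4)}, {f"G{i}" for i in range(4)}, "O"
        )
        o_res = res[0]
        assert o_res.mean_a == 2.0 and o_res.mean_b == 0.0
        assert o_res.p_value < 0.05  # exact enumeration, full separation at 4v4

    def test_carbon_control_always_included(self):
        contents = self.contents({"A": (0.5, 3.0), "B": (0.6, 3.1)})
        res = compare_groups(contents, {"A"}, {"B"}, "O")
        assert [r.element for r in res] == ["O", "C"]

    def test_overlapping_groups_rejected(self):
        contents = self.contents({"A": (0.5, 3.0), "B": (0.6, 3.1)})
        with pytest.raises(ValueError, match="overlap"):
            compare_groups(contents, {"A", "B"}, {"B"}, "O")

    def test_missing_profile_rejected(self):
        contents = self.contents({"A": (0.5, 3.0)})
        with pytest.raises(ValueError, match="without element profiles"):
            compare_groups(contents, {"A"}, {"Z"}, "O")
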