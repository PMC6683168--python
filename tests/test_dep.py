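"""DEP screening: ratios, moderated t, variance prior, BH-FDR, calls."""

import math

import numpy as np
import pytest
from scipy import stats

from stoichioprot.dep import (
    bh_fdr,
    call_deps,
    estimate_prior,
    log2_ratio,
    moderated_t,
    screen_deps,
)
from stoichioprot.scoring import build_expression_matrix
from stoichioprot.simulate import SyntheticConfig, generate_expression, generate_proteome


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "case,control,expected", [(8, 2, 2.0), (2, 2, 0.0), (1, 8, -3.0)]
    )
    def test_exact_values_without_pseudocount(self, case, control, expected):
        assert log2_ratio(case, control, pseudocount=0.0) == pytest.approx(expected)

    def test_pseudocount_guards_zero_control(self):
        assert log2_ratio(12.0, 0.0, pseudocount=0.1) == pytest.approx(
            math.log2(12.1 / 0.1)
        )

    def test_double_zero_without_pseudocount_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            log2_ratio(0.0, 0.0, pseudocount=0.0)


class TestModeratedT:
    def test_shrinkage_off_limit_matches_pooled_t_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = rng.normal(size=int(rng.integers(3, 10)))
            b = rng.normal(size=int(rng.integers(3, 10)))
            t_mod, p_mod = moderated_t(a, b, d0=0.0, s0_sq=0.0)
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
            assert t_mod == pytest.approx(t_ref, abs=1e-10)
            assert p_mod == pytest.approx(p_ref, abs=1e-10)

    def test_prior_dominates_limit_uses_s0_exactly(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 7.0])
        s0_sq = 2.0
        t, p = moderated_t(a, b, d0=math.inf, s0_sq=s0_sq)
        se = math.sqrt(s0_sq * (1 / 3 + 1 / 3))
        expected = (a.mean() - b.mean()) / se
        assert t == pytest.approx(expected)
        assert p == pytest.approx(2 * stats.norm.sf(abs(expected)))

    def test_degenerate_identical_groups(self):
        t, p = moderated_t([5.0, 5.0], [5.0, 5.0])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_but_separated_means(self):
        t, p = moderated_t([5.0, 5.0], [1.0, 1.0])
        assert math.isinf(t) and t > 0 and p == 0.0


class TestEstimatePrior:
    def test_equal_variances_give_infinite_d0(self):
        d0, s0_sq = estimate_prior([2.5] * 20, df=12)
        assert math.isinf(d0)
        assert s0_sq == pytest.approx(2.5)

    def test_recovers_generating_hyperparameters(self):
        rng = np.random.default_rng(42)
        d0_true, s0_true, d = 4.0, 1.0, 12
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(d, size=5000) / d
        d0, s0_sq = estimate_prior(s2, df=d)
        assert d0_true - 1 <= d0 <= d0_true + 1
        assert s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_too_few_variances_directs_to_unmoderated_mode(self):
        with pytest.raises(ValueError, match="d0=0"):
            estimate_prior([1.0, 2.0, 3.0, 4.0, 5.0], df=4)


class TestBhFdr:
    def test_step_up_hand_computation(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([1.0]), [1.0])

    def test_output_order_aligned_with_input(self):
        q = bh_fdr([0.05, 0.01])
        assert q[0] == pytest.approx(0.05)
        assert q[1] == pytest.approx(0.02)

    def test_q_dominates_p_and_max_q_is_max_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        assert q.max() == pytest.approx(p.max())

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCallDeps:
    @pytest.mark.parametrize(
        "lr,p,q,expected",
        [
            (2.0, 0.001, 0.005, "up"),
            (2.0, 0.2, 0.5, "none"),
            (-1.5, 0.001, 0.005, "down"),
            (0.5, 0.001, 0.005, "none"),  # fold gate fails
            (2.0, 0.001, 0.02, "none"),  # FDR gate fails
        ],
    )
    def test_combined_gates(self, lr, p, q, expected):
        (res,) = call_deps(["P1"], [lr], [1.0], [p], [q])
        assert res.call == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            call_deps(["P1"], [1.0, 2.0], [0.0], [0.5], [0.5])


class TestScreen:
    def test_noiseless_screen_recovers_planted_classes(self):
        config = SyntheticConfig(
            n_proteins=600, noise_sd=0.0, missing_rate=0.0, seed=5
        )
        records, truth = generate_proteome(config)
        observations = generate_expression(config, truth)
        matrix = build_expression_matrix(observations)
        case = [f"case_{i+1:02d}" for i in range(12)]
        ctrl = ["control_01", "control_02"]
        table = screen_deps(matrix, case, ctrl)
        merged = table.join(truth["planted_class"])
        planted = merged[merged["planted_class"].isin(["up", "down"])]
        recall = (planted["call"] == planted["planted_class"]).mean()
        assert recall >= 0.95
        null = merged[merged["planted_class"] == "null"]
        assert (null["call"] != "none").mean() <= 0.01
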