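"""Nonparametric battery: two-stage tests, effect sizes, power machinery."""

import numpy as np
import pytest
from scipy import stats as sps

from sonoderm import (
    PowerSpec,
    effect_size_r,
    estimate_sample_size,
    kruskal_dunn,
    mann_whitney,
    simulate_power,
    wilcoxon_signed_rank,
)
from sonoderm.stats import InsufficientDataError
import oracles


class TestWilcoxonSignedRank:
    def test_all_positive_n5_exact_one_sided(self):
        # extreme case: all five differences positive; exact one-sided
        # p = 1/32 (reachable through the gate at alpha=0.1, since the
        # two-sided p is 2/32)
        before = np.zeros(5)
        after = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(before, after, alpha=0.1)
        assert res.p_two_sided == pytest.approx(2 / 32)
        assert res.p_one_sided == pytest.approx(1 / 32)
        assert res.direction == "increase"

    def test_two_sided_gate_blocks_one_sided(self):
        before = np.zeros(5)
        after = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(before, after, alpha=0.05)
        assert res.p_one_sided is None  # 0.0625 >= 0.05

    def test_identical_pairs_error(self):
        x = np.arange(8.0)
        with pytest.raises(InsufficientDataError):
            wilcoxon_signed_rank(x, x)

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 11))
            before = rng.normal(size=n)
            after = before + rng.normal(size=n)
            res = wilcoxon_signed_rank(before, after, alpha=1.0)
            assert res.p_two_sided == pytest.approx(
                oracles.wilcoxon_exact_p(after - before))
            if res.p_one_sided is not None:  # gate passes unless p == 1
                alt = "greater" if res.direction == "increase" else "less"
                assert res.p_one_sided == pytest.approx(
                    oracles.wilcoxon_exact_p(after - before, alt))

    def test_two_stage_type_i_error_at_alpha(self):
        """The gate-then-direction procedure reports a directional finding
        at most at rate alpha under the null."""
        rng = np.random.default_rng(99)
        n_reps, n = 10_000, 20
        d = rng.normal(0.0, 1.0, size=(n_reps, n))
        p = sps.wilcoxon(d, axis=1, alternative="two-sided",
                         method="approx", correction=True).pvalue
        rate = (p < 0.05).mean()  # directional report iff two-sided rejects
        band = 2.576 * np.sqrt(0.05 * 0.95 / n_reps)
        assert rate <= 0.05 + band


class TestEffectSize:
    @pytest.mark.parametrize(
        "r,grade",
        [(0.2932, "small"), (0.3935, "moderate"), (0.5853, "large"),
         (0.4611, "moderate"), (0.7423, "large"), (0.4829, "moderate")],
    )
    def test_grades(self, r, grade):
        # feed z = r*sqrt(n) so the computed r equals the requested one
        got_r, got_grade = effect_size_r(r * np.sqrt(56), 56)
        assert got_r == pytest.approx(r)
        assert got_grade == grade

    def test_boundaries(self):
        assert effect_size_r(0.3, 1)[1] == "moderate"
        assert effect_size_r(0.5, 1)[1] == "large"
        assert effect_size_r(0.29999, 1)[1] == "small"


class TestMannWhitney:
    def test_identical_groups_no_followup(self):
        a = np.arange(10.0)
        res = mann_whitney(a + 0.25, a)  # interleaved, symmetric
        assert res.p_two_sided > 0.5
        assert res.p_one_sided is None

    def test_disjoint_groups_exact(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 11.0, 12.0, 13.0])
        res = mann_whitney(a, b, alpha=0.05)
        assert res.p_two_sided == pytest.approx(2 / 70)
        assert res.p_one_sided == pytest.approx(1 / 70)
        assert res.direction == "decrease"

    def test_label_swap_symmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(1.0, 1.0, size=7)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(b, a)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)
        assert {r1.direction, r2.direction} == {"increase", "decrease"}

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(30):
            n1, n2 = int(rng.integers(3, 11)), int(rng.integers(3, 11))
            a = rng.normal(size=n1)
            b = rng.normal(0.5, 1.0, size=n2)
            res = mann_whitney(a, b, alpha=1.0)
            assert res.p_two_sided == pytest.approx(oracles.mann_whitney_exact_p(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([], [1.0, 2.0, 3.0])


class TestKruskalDunn:
    def test_null_non_rejection_rate(self):
        rng = np.random.default_rng(7)
        n_seeds, alpha = 500, 0.05
        rejections = sum(
            kruskal_dunn(
                {s: rng.normal(size=12) for s in (1, 2, 3)}, alpha
            ).omnibus_rejected
            for _ in range(n_seeds)
        )
        rate = rejections / n_seeds
        band = 2.576 * np.sqrt(alpha * (1 - alpha) / n_seeds)
        assert abs(rate - alpha) <= band

    def test_two_groups_dunn_equals_mann_whitney_z(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(2.0, 1.0, 12)  # separated so the omnibus rejects
        res = kruskal_dunn({"a": a, "b": b}, alpha=0.05, adjust="none")
        assert res.omnibus_rejected
        mw = sps.mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic", use_continuity=False)
        assert res.pairwise["p_raw"].iloc[0] == pytest.approx(float(mw.pvalue))

    def test_shifted_group_flagged_in_both_pairs(self, rng):
        groups = {1: rng.normal(0, 1, 15), 2: rng.normal(0, 1, 15),
                  3: rng.normal(5, 1, 15)}
        res = kruskal_dunn(groups)
        assert res.omnibus_rejected
        pw = res.pairwise
        flag = lambda a, b: pw[(pw.group_a == a) & (pw.group_b == b)]["significant"].iloc[0]
        assert flag(1, 3) and flag(2, 3) and not flag(1, 2)

    def test_tiny_group_excluded_with_warning(self, rng):
        res = kruskal_dunn({1: rng.normal(size=10), 2: rng.normal(size=10), 3: [1.0]})
        assert res.excluded_groups == [3]
        assert any("n=1" in w for w in res.warnings)

    def test_fewer_than_two_groups_error(self):
        with pytest.raises(InsufficientDataError):
            kruskal_dunn({1: [1.0, 2.0], 2: [3.0]})


class TestSampleSize:
    def test_t_test_n(self):
        assert estimate_sample_size(PowerSpec(are_method="none")) == 44

    def test_min_are_n(self):
        assert estimate_sample_size(PowerSpec(are_method="min_are")) == 51

    def test_normal_are_n(self):
        assert estimate_sample_size(PowerSpec(are_method="normal_are")) == 47

    def test_tiny_power_returns_minimal_n(self):
        # any positive effect gives power >= alpha already at the smallest
        # legal size, so the search bottoms out at n = 2
        assert estimate_sample_size(PowerSpec(power=0.051)) <= 3

    def test_monotone_in_effect_and_power(self):
        base = estimate_sample_size(PowerSpec())
        assert estimate_sample_size(PowerSpec(effect_dz=0.8)) <= base
        assert estimate_sample_size(PowerSpec(power=0.95)) >= base

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(effect_dz=-1.0)


class TestSimulatePower:
    def test_null_size(self):
        spec = PowerSpec(effect_dz=0.5)
        spec.effect_dz = 1e-12  # effectively the null
        power = simulate_power(spec, n=30, n_reps=1000, seed=5)
        band = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(power - 0.05) <= band

    def test_monotone_in_n(self):
        spec = PowerSpec()
        powers = [simulate_power(spec, n, n_reps=1500, seed=8) for n in (10, 25, 51)]
        assert powers[0] < powers[1] < powers[2]

    def test_reproducible(self):
        spec = PowerSpec()
        assert simulate_power(spec, 20, 500, seed=1) == simulate_power(spec, 20, 500, seed=1)
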