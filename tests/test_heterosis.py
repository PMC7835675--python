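import numpy as np
import pytest
from scipy import stats

from ploidmeth.bisulfite import MethylationSummary
from ploidmeth.heterosis import (CrossDesign, ParentSpec, Pattern, ReplicateSet,
                                 classify_expression_pattern, compute_mpv,
                                 ddct_relative_expression, methylation_mpv_trend,
                                 one_way_anova)
from ploidmeth.simulate import simulate_expression_trio


def _rs(genotype, values, trait="expr"):
    return ReplicateSet(genotype, trait, tuple(values))


class TestMpv:
    def test_weighted_combination(self, design):
        assert compute_mpv(30.0, 12.0, design) == pytest.approx(24.0)

    def test_identity_for_equal_parents(self, design):
        assert compute_mpv(7.3, 7.3, design) == pytest.approx(7.3)

    def test_percent_scale_combination(self, design):
        assert compute_mpv(21.0, 22.5, design) == pytest.approx(21.5, abs=1e-9)

    def test_bounded_between_parents(self, rng, design):
        for _ in range(50):
            a, b = rng.uniform(0, 100, size=2)
            mpv = compute_mpv(a, b, design)
            assert min(a, b) - 1e-12 <= mpv <= max(a, b) + 1e-12

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            CrossDesign("h", ParentSpec("a", 0.5), ParentSpec("b", 0.4))


class TestAnova:
    def test_identical_constant_groups(self):
        res = one_way_anova([_rs("a", [5, 5, 5]), _rs("b", [5, 5, 5])])
        assert res.f == 0.0 and res.p == 1.0

    def test_equal_means_zero_f(self):
        res = one_way_anova([_rs("a", [1, 2, 3]), _rs("b", [1, 2, 3])])
        assert res.f == pytest.approx(0.0)

    def test_textbook_sums_of_squares(self):
        # groups {0,1,2} and {10,11,12}: SSB = 150, SSW = 4, F = 150
        res = one_way_anova([_rs("a", [0, 1, 2]), _rs("b", [10, 11, 12])])
        assert res.f == pytest.approx(150.0)
        assert res.p == pytest.approx(stats.f.sf(150.0, 1, 4))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([_rs("a", [1.0]), _rs("b", [1, 2])])

    def test_f_equals_t_squared_on_two_groups(self, rng):
        """One-way ANOVA of two groups is the pooled-variance t test: F = t^2."""
        for _ in range(100):
            a = rng.normal(0, 1, size=int(rng.integers(3, 8)))
            b = rng.normal(rng.uniform(-2, 2), 1, size=int(rng.integers(3, 8)))
            res = one_way_anova([_rs("a", a), _rs("b", b)])
            t, p = stats.ttest_ind(a, b, equal_var=True)
            assert res.f == pytest.approx(t ** 2, rel=1e-9)
            assert res.p == pytest.approx(p, rel=1e-9)


class TestClassification:
    def test_hybrid_at_mpv_is_additive(self, design):
        p1 = _rs("LQ1-4x", [2.0, 2.02, 1.98])
        p2 = _rs("GC-1", [1.0, 1.01, 0.99])
        mpv = compute_mpv(p1.mean, p2.mean, design)
        hybrid = _rs("A-3", [mpv, mpv, mpv])
        call = classify_expression_pattern(hybrid, p1, p2, design)
        assert call.pattern == Pattern.MPL

    def test_hybrid_far_above_both_parents_is_ahp(self, design):
        p1 = _rs("LQ1-4x", [2.0, 2.1, 1.9])
        p2 = _rs("GC-1", [1.0, 1.05, 0.95])
        hybrid = _rs("A-3", [5.0, 5.1, 4.9])
        call = classify_expression_pattern(hybrid, p1, p2, design)
        assert call.pattern == Pattern.AHP
        assert call.hp == pytest.approx(2.0) and call.lp == pytest.approx(1.0)

    def test_hybrid_far_below_both_parents_is_blp(self, design):
        p1 = _rs("LQ1-4x", [2.0, 2.1, 1.9])
        p2 = _rs("GC-1", [1.0, 1.05, 0.95])
        hybrid = _rs("A-3", [0.2, 0.21, 0.19])
        call = classify_expression_pattern(hybrid, p1, p2, design)
        assert call.pattern == Pattern.BLP

    def test_hybrid_at_high_parent_is_hpl(self, design):
        p1 = _rs("LQ1-4x", [2.0, 2.05, 1.95])
        p2 = _rs("GC-1", [1.0, 1.02, 0.98])
        hybrid = _rs("A-3", [2.0, 2.04, 1.96])
        call = classify_expression_pattern(hybrid, p1, p2, design)
        assert call.pattern == Pattern.HPL

    def test_parent_argument_order_does_not_matter(self, design):
        """Parents are matched to the design by genotype, so swapping the
        argument order changes nothing."""
        p1 = _rs("LQ1-4x", [2.0, 2.1, 1.9])
        p2 = _rs("GC-1", [1.0, 1.05, 0.95])
        hybrid = _rs("A-3", [5.0, 5.1, 4.9])
        a = classify_expression_pattern(hybrid, p1, p2, design)
        b = classify_expression_pattern(hybrid, p2, p1, design)
        assert a == b

    def test_classification_is_exhaustive(self, rng, design):
        """Any replicate input yields exactly one pattern."""
        for _ in range(50):
            groups = [_rs(g, rng.uniform(0.1, 3.0, size=3))
                      for g in ("A-3", "LQ1-4x", "GC-1")]
            call = classify_expression_pattern(*groups, design)
            assert call.pattern in Pattern

    def test_zero_variance_with_unequal_means_is_significant_and_flagged(self, design):
        p1 = _rs("LQ1-4x", [2.0, 2.0, 2.0])
        p2 = _rs("GC-1", [1.0, 1.0, 1.0])
        hybrid = _rs("A-3", [3.0, 3.0, 3.0])
        call = classify_expression_pattern(hybrid, p1, p2, design)
        assert call.pattern == Pattern.AHP and call.degenerate

    def test_small_replicate_sets_rejected(self, design):
        with pytest.raises(ValueError, match="n = 2"):
            classify_expression_pattern(_rs("A-3", [1, 2]), _rs("LQ1-4x", [1, 2, 3]),
                                        _rs("GC-1", [1, 2, 3]), design)

    def test_alpha_validated(self, design):
        groups = [_rs(g, [1.0, 1.1, 0.9]) for g in ("A-3", "LQ1-4x", "GC-1")]
        with pytest.raises(ValueError, match="alpha"):
            classify_expression_pattern(*groups, design, alpha=0.9)

    def test_blp_recovery_deep_below_low_parent(self, rng, design):
        """A hybrid at half the low-parent level (CV 5%, n = 3) is called BLP
        essentially always."""
        hits = 0
        n = 400
        for _ in range(n):
            hyb, p_hi, p_lo, _ = simulate_expression_trio(
                "BLP", effect_size=6.0, cv=0.05, rng=rng, design=design)
            assert min(hyb.values) > 0
            call = classify_expression_pattern(hyb, p_hi, p_lo, design)
            hits += call.pattern == Pattern.BLP
        assert hits / n >= 0.95

    def test_class_recovery_at_well_powered_effect(self, design):
        """At effect size 5 (where the one-sided pooled comparison has power
        ~0.999) the over-dominance classes are recovered essentially always;
        dominance/additive classes sit near their alpha-limited ceilings
        (~0.93), so balanced recovery clears 0.90 comfortably."""
        import numpy as np
        rng = np.random.default_rng(20240902)
        per = {}
        for cls in ("MPL", "HPL", "LPL", "AHP", "BLP"):
            ok = 0
            for _ in range(200):
                hyb, p_hi, p_lo, _ = simulate_expression_trio(
                    cls, effect_size=5.0, cv=0.05, rng=rng, design=design)
                ok += classify_expression_pattern(
                    hyb, p_hi, p_lo, design).pattern.value == cls
            per[cls] = ok / 200
        assert per["AHP"] >= 0.95 and per["BLP"] >= 0.95
        assert sum(per.values()) / 5 >= 0.90

    def test_welch_method_agrees_on_clear_cases(self, design):
        p1 = _rs("LQ1-4x", [2.0, 2.1, 1.9])
        p2 = _rs("GC-1", [1.0, 1.05, 0.95])
        hybrid = _rs("A-3", [5.0, 5.1, 4.9])
        call = classify_expression_pattern(hybrid, p1, p2, design, method="welch")
        assert call.pattern == Pattern.AHP


class TestDdct:
    @pytest.mark.parametrize("ct_t, ct_r, delta, expected", [
        (20.0, 20.0, 0.0, 1.0),
        (21.0, 20.0, 0.0, 0.5),
        (18.0, 20.0, 0.0, 4.0),
        (22.0, 20.0, 2.0, 1.0),
    ])
    def test_examples(self, ct_t, ct_r, delta, expected):
        assert ddct_relative_expression(ct_t, ct_r, delta) == pytest.approx(expected)


def _summary(genotype, scope, cg, chg, chh):
    # each context given as (methylated, assayed)
    return MethylationSummary(genotype, scope,
                              {"CG": cg, "CHG": chg, "CHH": chh})


class TestTrend:
    def test_total_percent_decrease_vs_mpv(self, design):
        """Hybrid total 17.56% against a parental MPV of 21.50% -> decrease."""
        hyb = [_summary("A-3", "TOTAL", (439, 2500), (0, 0), (0, 0))]
        p_hi = [_summary("LQ1-4x", "TOTAL", (210, 1000), (0, 0), (0, 0))]
        p_lo = [_summary("GC-1", "TOTAL", (900, 4000), (0, 0), (0, 0))]
        reports = methylation_mpv_trend(hyb, p_hi, p_lo, design)
        total = next(r for r in reports if r.context == "ALL")
        assert total.hybrid_value == pytest.approx(0.1756)
        assert total.mpv_value == pytest.approx(0.2150)
        assert total.direction == "decrease"

    def test_equal_to_mpv_is_unchanged(self, design):
        s = [(10, 100), (5, 50), (2, 20)]
        hyb = [_summary("A-3", "TOTAL", *s)]
        p = [_summary("LQ1-4x", "TOTAL", *s)]
        q = [_summary("GC-1", "TOTAL", *s)]
        reports = methylation_mpv_trend(hyb, p, q, design)
        assert all(r.direction == "unchanged" for r in reports)

    def test_one_island_can_increase_while_total_decreases(self, design):
        hyb = [_summary("A-3", "CpG2", (30, 100), (1, 10), (1, 10)),
               _summary("A-3", "TOTAL", (10, 200), (1, 20), (1, 20))]
        p_hi = [_summary("LQ1-4x", "CpG2", (20, 100), (1, 10), (1, 10)),
                _summary("LQ1-4x", "TOTAL", (40, 200), (2, 20), (2, 20))]
        p_lo = [_summary("GC-1", "CpG2", (20, 100), (1, 10), (1, 10)),
                _summary("GC-1", "TOTAL", (44, 200), (2, 20), (2, 20))]
        reports = {(r.scope, r.context): r.direction
                   for r in methylation_mpv_trend(hyb, p_hi, p_lo, design)}
        assert reports[("CpG2", "CG")] == "increase"
        assert reports[("TOTAL", "ALL")] == "decrease"

    def test_dead_band_maps_small_changes_to_unchanged(self, design):
        hyb = [_summary("A-3", "TOTAL", (21, 100), (0, 10), (0, 10))]
        p = [_summary("LQ1-4x", "TOTAL", (20, 100), (0, 10), (0, 10))]
        q = [_summary("GC-1", "TOTAL", (20, 100), (0, 10), (0, 10))]
        with_band = methylation_mpv_trend(hyb, p, q, design, dead_band=0.05)
        assert all(r.direction == "unchanged" for r in with_band)

    def test_scope_mismatch_rejected(self, design):
        hyb = [_summary("A-3", "CpG1", (1, 10), (1, 10), (1, 10))]
        p = [_summary("LQ1-4x", "CpG9", (1, 10), (1, 10), (1, 10))]
        with pytest.raises(ValueError, match="scope"):
            methylation_mpv_trend(hyb, p, p, design)
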