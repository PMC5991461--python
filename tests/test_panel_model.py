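"""Panel construction, summaries, trimming, bootstrap SEs, diagnostics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchorcut import (
    InsufficientPanelError,
    JudgePanel,
    JudgeRating,
    PanelValidationError,
    bootstrap_se,
    normality_diagnostics,
    summarize_panel,
    trim_extremes,
)
from conftest import PILOT, build_panel


def panel_from_arrays(L, H, suggested=None, **kwargs):
    return JudgePanel(
        [
            JudgeRating(
                f"j{i}", float(L[i]), float(H[i]),
                None if suggested is None else float(suggested[i]),
            )
            for i in range(len(L))
        ],
        **kwargs,
    )


class TestPanelValidation:
    def test_duplicate_judge_id_rejected(self):
        with pytest.raises(PanelValidationError, match="duplicate"):
            JudgePanel([JudgeRating("a", 50, 60), JudgeRating("a", 40, 70)])

    @pytest.mark.parametrize("field,value", [("L", -1), ("H", 101), ("suggested", 120)])
    def test_out_of_range_names_judge(self, field, value):
        kwargs = {"L": 50.0, "H": 60.0, "suggested": 55.0, field: value}
        with pytest.raises(PanelValidationError, match="'bad'"):
            JudgePanel([JudgeRating("bad", **kwargs)])

    def test_inconsistent_judge_retained_by_default(self, caplog):
        with caplog.at_level("WARNING"):
            panel = JudgePanel([JudgeRating("a", 70, 60), JudgeRating("b", 50, 60)])
        assert len(panel) == 2
        assert "L > H" in caplog.text

    def test_inconsistent_judge_dropped_on_request(self):
        panel = JudgePanel(
            [JudgeRating("a", 70, 60), JudgeRating("b", 50, 60),
             JudgeRating("c", 40, 65)],
            drop_inconsistent=True,
        )
        assert len(panel) == 2
        assert panel.removed_judge_ids == ("a",)


class TestSummarize:
    def test_zero_variance_panel(self):
        panel = panel_from_arrays([60, 60, 60], [70, 70, 70])
        s = summarize_panel(panel)
        assert (s.mean_L, s.sd_L, s.se_L) == (60, 0, 0)
        assert (s.mean_H, s.se_H) == (70, 0)

    def test_two_judge_hand_computation(self):
        # sample SD of {60, 70} = sqrt(50) ~ 7.0711; SE = SD/sqrt(2) = 5
        s = summarize_panel(panel_from_arrays([60, 70], [65, 75]))
        assert s.mean_L == 65
        assert s.sd_L == pytest.approx(7.0711, abs=1e-4)
        assert s.se_L == pytest.approx(5.0, abs=1e-12)

    def test_reproduces_pilot_clear_pass_moments(self):
        panel = build_panel(
            PILOT["mean_L"], PILOT["se_L"], PILOT["mean_H"], PILOT["se_H"],
            n=17, seed=3,
        )
        s = summarize_panel(panel)
        assert s.mean_H == pytest.approx(65.35, abs=5e-3)
        assert s.se_H == pytest.approx(3.193, abs=5e-3)

    def test_insufficient_panel(self):
        with pytest.raises(InsufficientPanelError):
            summarize_panel(JudgePanel([JudgeRating("a", 50, 60)]))

    def test_suggested_absent_when_any_missing(self):
        panel = JudgePanel(
            [JudgeRating("a", 50, 60, 55), JudgeRating("b", 52, 62, None)]
        )
        s = summarize_panel(panel)
        assert s.mean_suggested is None and s.se_suggested is None

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 100, allow_nan=False),
            ),
            min_size=2,
            max_size=40,
        )
    )
    def test_matches_two_pass_brute_force(self, data):
        """Means/SDs/SEs agree with an explicit two-pass computation."""
        panel = panel_from_arrays([d[0] for d in data], [d[1] for d in data])
        s = summarize_panel(panel)
        n = len(data)
        for values, mean, sd, se in [
            (panel.L, s.mean_L, s.sd_L, s.se_L),
            (panel.H, s.mean_H, s.sd_H, s.se_H),
        ]:
            m = sum(values) / n
            var = sum((v - m) ** 2 for v in values) / (n - 1)
            assert mean == pytest.approx(m, abs=1e-12)
            assert sd == pytest.approx(math.sqrt(var), abs=1e-12)
            assert se == pytest.approx(math.sqrt(var / n), abs=1e-12)

    def test_order_invariance_and_duplication(self):
        panel = build_panel(60, 4, 70, 3, n=12, seed=5)
        rev = JudgePanel(tuple(reversed(panel.ratings)))
        s, sr = summarize_panel(panel), summarize_panel(rev)
        assert s.se_L == pytest.approx(sr.se_L, abs=1e-12)
        assert s.mean_H == pytest.approx(sr.mean_H, abs=1e-12)
        # doubling the panel keeps means, shrinks SEs by ~1/sqrt(2)
        doubled = JudgePanel(
            panel.ratings
            + tuple(
                JudgeRating(f"d{r.judge_id}", r.L, r.H) for r in panel.ratings
            )
        )
        sd2 = summarize_panel(doubled)
        assert sd2.mean_L == pytest.approx(s.mean_L, abs=1e-12)
        assert sd2.se_L == pytest.approx(s.se_L / math.sqrt(2), rel=0.05)


class TestTrim:
    def test_k_zero_is_identity(self):
        panel = build_panel(60, 4, 70, 3, n=7)
        assert trim_extremes(panel, 0) is panel

    def test_removes_order_statistics(self):
        panel = panel_from_arrays([10, 60, 61, 62, 99], [50, 65, 66, 67, 90])
        trimmed = trim_extremes(panel, 1, field="L")
        assert list(trimmed.L) == [60, 61, 62]
        assert set(trimmed.removed_judge_ids) == {"j0", "j4"}
        assert len(panel) == 5  # original untouched

    def test_whole_judges_removed(self):
        panel = panel_from_arrays([10, 60, 61, 62, 99], [50, 65, 66, 67, 90])
        trimmed = trim_extremes(panel, 1, field="L")
        assert list(trimmed.H) == [65, 66, 67]

    def test_over_trim_errors(self):
        panel = build_panel(60, 4, 70, 3, n=5)
        with pytest.raises(InsufficientPanelError):
            trim_extremes(panel, 2)

    def test_ties_broken_by_input_order(self):
        panel = panel_from_arrays([50, 50, 50, 80, 80], [60, 61, 62, 85, 86])
        trimmed = trim_extremes(panel, 1, field="L")
        # first tied-low judge (j0) and first tied-high judge (j3) go
        assert set(trimmed.removed_judge_ids) == {"j0", "j3"}

    def test_trim_then_summarize_equals_manual_filter(self):
        panel = build_panel(60, 6, 70, 4, n=11, seed=9)
        trimmed = trim_extremes(panel, 2, field="H")
        manual = JudgePanel(
            [r for r in panel.ratings if r.judge_id in
             {t.judge_id for t in trimmed.ratings}]
        )
        s1, s2 = summarize_panel(trimmed), summarize_panel(manual)
        assert s1.mean_H == pytest.approx(s2.mean_H, abs=1e-12)
        assert s1.se_L == pytest.approx(s2.se_L, abs=1e-12)
        assert s1.trimmed and s1.n_trimmed == 4


class TestBootstrapSE:
    def test_constant_values_give_zero(self):
        assert bootstrap_se([5, 5, 5, 5], replicates=50, seed=1) == 0.0

    def test_matches_exhaustive_enumeration_at_n2(self):
        """For {0, 10} the exact bootstrap SE is the spread of the four
        equally likely resample means {0, 5, 5, 10}; the Monte-Carlo
        estimator converges to it."""
        values = [0.0, 10.0]
        means = [np.mean(r) for r in itertools.product(values, repeat=2)]
        exact = float(np.std(means))  # population SD of the enumeration
        assert exact == pytest.approx(math.sqrt(12.5), abs=1e-12)
        estimate = bootstrap_se(values, replicates=40000, seed=7)
        assert estimate == pytest.approx(exact, rel=0.03)

    def test_converges_to_analytic_se_on_normal_data(self):
        rng = np.random.default_rng(42)
        values = rng.normal(62.65, 23.12, size=17)
        analytic = np.std(values, ddof=1) / math.sqrt(17)
        assert bootstrap_se(values, replicates=5000, seed=3) == pytest.approx(
            analytic, rel=0.15
        )

    def test_reproducible_for_fixed_seed(self):
        values = [3.0, 9.0, 12.0, 20.0]
        a = bootstrap_se(values, replicates=500, seed=11)
        b = bootstrap_se(values, replicates=500, seed=11)
        assert a == b
        assert bootstrap_se(values, replicates=500, seed=12) != a

    def test_insufficient_values(self):
        with pytest.raises(InsufficientPanelError):
            bootstrap_se([5.0], replicates=10, seed=0)


class TestNormalityDiagnostics:
    def test_symmetric_values_have_zero_skew(self):
        report = normality_diagnostics([1, 2, 3])
        assert report.skewness == pytest.approx(0.0, abs=1e-12)

    def test_heavy_right_tail_flags(self):
        report = normality_diagnostics([1, 1, 1, 10])
        assert report.skewness > 1
        assert report.advisory

    def test_too_few_values(self):
        with pytest.raises(PanelValidationError):
            normality_diagnostics([1, 2])

    def test_calibration_on_normal_draws(self):
        """On genuinely normal samples the advisory flag should be quiet
        in at least 90% of seeded repeats."""
        flags = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=1000)
            flags += normality_diagnostics(x).advisory
        assert flags <= 10
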