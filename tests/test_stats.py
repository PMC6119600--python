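"""Normalization, SEM summaries, t-test, ANOVA + Bonferroni."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitoring.stats import (
    anova_bonferroni,
    normalize_to_control,
    summarize,
    t_test_two_tailed,
)


class TestNormalizeToControl:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["experiment", "group", "value"])

    def test_treated_divided_by_control(self):
        df = self.frame([(1, "ctrl", 2.0), (1, "treated", 3.0)])
        out = normalize_to_control(df, "ctrl")
        assert out.loc[out.group == "treated", "normalized"].item() == pytest.approx(1.5)
        assert out.loc[out.group == "ctrl", "normalized"].item() == pytest.approx(1.0)

    def test_ratio_of_ratios(self):
        # phospho/total relative to a control with phospho/total = 1
        df = self.frame([(1, "ctrl", 100 / 100), (1, "treated", 50 / 100)])
        out = normalize_to_control(df, "ctrl")
        assert out.loc[out.group == "treated", "normalized"].item() == pytest.approx(0.5)

    def test_per_experiment_scaling(self):
        df = self.frame(
            [(1, "ctrl", 2.0), (1, "t", 4.0), (2, "ctrl", 10.0), (2, "t", 5.0)]
        )
        out = normalize_to_control(df, "ctrl")
        assert list(out.loc[out.group == "t", "normalized"]) == pytest.approx([2.0, 0.5])

    def test_zero_control_errors_naming_experiment(self):
        df = self.frame([(7, "ctrl", 0.0), (7, "t", 1.0)])
        with pytest.raises(ValueError, match="7"):
            normalize_to_control(df, "ctrl")

    def test_missing_control_errors(self):
        df = self.frame([(1, "ctrl", 1.0), (1, "t", 2.0), (2, "t", 2.0)])
        with pytest.raises(ValueError, match="control"):
            normalize_to_control(df, "ctrl")


class TestSummarize:
    def test_closed_form_sem(self):
        s = summarize([1, 2, 3])
        assert s.mean == pytest.approx(2.0)
        assert s.sem == pytest.approx(1 / math.sqrt(3))

    def test_equal_values_have_zero_sem(self):
        assert summarize([5, 5, 5, 5]).sem == 0.0

    def test_single_value_sem_missing(self):
        s = summarize([3.2])
        assert s.mean == 3.2 and math.isnan(s.sem)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            summarize([])


class TestTTest:
    def test_identical_groups_give_unity_p(self):
        res = t_test_two_tailed([1, 2, 3], [1, 2, 3])
        assert res.p_raw == pytest.approx(1.0)

    def test_pooled_worked_example(self):
        # hand computation: means 2 and 3, each sample variance 1,
        # pooled SE = sqrt(2/3), t = -1/sqrt(2/3)
        res = t_test_two_tailed([1, 2, 3], [2, 3, 4], variance="pooled")
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4
        assert res.p_raw == pytest.approx(0.2879, abs=1e-3)

    def test_zero_variance_equal_means_not_an_error(self):
        res = t_test_two_tailed([2, 2, 2], [2, 2, 2])
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            t_test_two_tailed([1], [1, 2])

    def test_null_type_one_error_calibrated(self):
        # 1000 null replicates, two N(0,1) groups of 35: rejection rate at
        # alpha=0.05 must sit inside the 99% binomial band
        rng = np.random.default_rng(2024)
        rejections = 0
        a = rng.normal(size=(1000, 35))
        b = rng.normal(size=(1000, 35))
        from scipy import stats as sps

        p = sps.ttest_ind(a, b, axis=1).pvalue
        rate = float((p < 0.05).mean())
        assert 0.035 <= rate <= 0.065


class TestAnovaBonferroni:
    GROUPS = {"g1": [0, 1, 2], "g2": [1, 2, 3], "g3": [2, 3, 4]}

    def test_worked_example_f_and_p(self):
        # SS_between = 6, SS_within = 6, df (2, 6) -> F = 3.0
        res = anova_bonferroni(self.GROUPS, family="all_pairs")
        assert res.anova.statistic == pytest.approx(3.0)
        assert res.anova.df == (2.0, 6.0)
        assert res.anova.p_raw == pytest.approx(0.125, abs=0.005)

    def test_family_size_vs_reference_four_rings(self):
        groups = {f"ring{k}": [k, k + 1, k + 2] for k in range(1, 5)}
        res = anova_bonferroni(groups, family="vs_reference", reference="ring1")
        assert all(c.family_size == 3 for c in res.pairwise)
        assert len(res.pairwise) == 3

    def test_family_size_all_pairs_four_groups(self):
        groups = {f"g{k}": [k, k + 1, k + 2] for k in range(4)}
        res = anova_bonferroni(groups, family="all_pairs")
        assert len(res.pairwise) == 6
        assert all(c.family_size == 6 for c in res.pairwise)

    def test_two_identical_groups_give_zero_f(self):
        res = anova_bonferroni({"a": [1, 2, 3], "b": [1, 2, 3]}, family="all_pairs")
        assert res.anova.statistic == pytest.approx(0.0)
        assert res.anova.p_raw == pytest.approx(1.0)

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=20), rng.normal(0.4, 1, size=25)
        res = anova_bonferroni({"a": a, "b": b}, family="all_pairs")
        t = t_test_two_tailed(a, b, variance="pooled")
        assert res.anova.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.anova.p_raw == pytest.approx(t.p_raw, rel=1e-9)

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            anova_bonferroni(self.GROUPS, family="vs_reference", reference="nope")

    def test_family_mode_is_required(self):
        with pytest.raises(ValueError):
            anova_bonferroni(self.GROUPS, family="sometimes")


@settings(deadline=None, derandomize=True, max_examples=40)
@given(m=st.integers(min_value=1, max_value=50))
def test_bonferroni_never_decreases_and_caps_at_one(m):
    res = t_test_two_tailed([1.0, 2.0, 3.0], [1.4, 2.1, 3.3], family_size=m)
    assert res.p_adjusted == pytest.approx(min(1.0, res.p_raw * m))
    assert res.p_raw <= res.p_adjusted <= 1.0


def test_pipeline_power_on_programmed_effect(vehicle_segmented):
    """A 25% programmed ratio effect at n=35 cells/group is detected in
    >=90% of 200 resampled replicates, with per-cell values drawn from
    fields rendered at the default noise level."""
    from mitoring.metrics import whole_cell_metrics
    from mitoring.segment import segment_image
    from mitoring.synthetic import generate_scene, render, scenario_preset

    seg, corr = vehicle_segmented
    base = [m.ratio_potential_marker for m in whole_cell_metrics(seg, corr) if m.valid]
    for seed in (12, 13):
        scene = generate_scene(scenario_preset("vehicle", seed=seed))
        s, c = segment_image(render(scene))
        base += [m.ratio_potential_marker for m in whole_cell_metrics(s, c) if m.valid]
    base = np.asarray(base)
    assert base.size >= 10
    treated_pool = base * 1.25
    rng = np.random.default_rng(77)
    hits = 0
    for _ in range(200):
        a = rng.choice(base, size=35, replace=True)
        b = rng.choice(treated_pool, size=35, replace=True)
        if t_test_two_tailed(a, b).p_adjusted < 0.05:
            hits += 1
    assert hits >= 180
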