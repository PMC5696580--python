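"""Statistical battery: Spearman, Mann-Whitney, severity, matched subsets."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from osakit import cohort, stats
from osakit.stats import (
    MatchedSubsetSpec,
    SeverityPolicy,
    assign_severity,
    build_matched_subset,
    correlation_table,
    fowler_label,
    mann_whitney,
    render_contrast_table,
    render_correlation_table,
    render_descriptive_table,
    spearman,
)


class TestSpearman:
    def test_identity_is_one(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        res = spearman(x, x)
        assert res.r == pytest.approx(1.0)

    def test_hand_rank_oracle_integer_example(self):
        """r equals 1 - 6*sum(d^2)/(n(n^2-1)) on tie-free integer data."""
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        d2 = sum((a - b) ** 2 for a, b in zip(x, y))
        expected = 1 - 6 * d2 / (5 * 24)
        assert spearman(x, y).r == pytest.approx(expected)  # 0.8
        assert expected == 0.8

    def test_scipy_cross_check(self, rng):
        x = rng.standard_normal(80)
        y = 0.5 * x + rng.standard_normal(80)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_small_n(self):
        """Small-sample p matches scipy's exact permutation distribution."""
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 3, 5, 4, 6]
        res = spearman(x, y)
        ref = sps.spearmanr(x, y, alternative="two-sided")
        # scipy uses the exact null for n <= 1290 without ties via betainc?
        # compare instead against brute-force enumeration here
        rx = np.array(x, dtype=float)
        ry = np.array(y, dtype=float)
        obs = abs(res.r)
        count = total = 0
        for perm in itertools.permutations(ry):
            rp = np.corrcoef(rx, perm)[0, 1]
            count += abs(rp) >= obs - 1e-12
            total += 1
        assert res.p == pytest.approx(count / total)

    def test_ties_use_midranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0]
        y = [1.0, 3.0, 2.0, 4.0, 4.0, 5.0, 7.0, 6.0, 8.0, 9.0, 11.0, 10.0]
        assert spearman(x, y).r == pytest.approx(
            sps.spearmanr(x, y).statistic, abs=1e-12
        )

    @pytest.mark.parametrize("r,label", [
        (0.1, "very weak"), (0.19, "very weak"), (0.2, "weak"), (0.39, "weak"),
        (0.40, "modest"), (0.52, "modest"), (0.69, "modest"), (0.70, "strong"),
        (0.89, "strong"), (0.90, "very strong"), (-0.52, "modest"),
    ])
    def test_fowler_bins(self, r, label):
        assert fowler_label(r) == label

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0] * 6, [1, 2, 3, 4, 5, 6])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])

    @given(st.sampled_from(["exp", "cube", "logit"]))
    def test_monotone_transform_invariance(self, name):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(40)
        y = x + rng.standard_normal(40)
        f = {"exp": np.exp, "cube": lambda v: v**3,
             "logit": lambda v: 1 / (1 + np.exp(-v))}[name]
        assert spearman(f(x), y).r == pytest.approx(spearman(x, y).r, abs=1e-12)


class TestCorrelationTable:
    def test_null_calibration(self, rng):
        """With independent variables ~5% of cells reach the .05 tier."""
        n = 1000
        df = pd.DataFrame(rng.standard_normal((n, 20)),
                          columns=[f"v{i}" for i in range(20)])
        results = correlation_table(df, [f"v{i}" for i in range(10)],
                                    [f"v{i}" for i in range(10, 20)])
        frac = np.mean([r.tier != "ns" for r in results])
        assert 0.01 <= frac <= 0.10

    def test_reference_cohort_age_ahi_marked_01(self, female_cohort_frame):
        results = correlation_table(female_cohort_frame, ["age"], ["ahi"])
        assert results[0].tier == ".01"
        table = render_correlation_table(results)
        assert table.loc["age", "ahi"].endswith("**")

    def test_printed_cells_pass_critical_value_oracle(self, female_cohort_frame):
        """Every rendered |r| exceeds the t-approximation critical value."""
        results = correlation_table(
            female_cohort_frame,
            ["cervicomental_ratio", "face_width_ratio", "trs_angle"],
            ["ahi", "age", "bmi"],
        )
        for res in results:
            if res.tier == "ns":
                continue
            tcrit = sps.t.ppf(1 - 0.025, res.n - 2)
            rcrit = tcrit / np.sqrt(res.n - 2 + tcrit**2)
            assert abs(res.r) >= rcrit

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            correlation_table(pd.DataFrame(), [], [])


class TestMannWhitney:
    def test_full_tie_gives_half(self):
        res = mann_whitney([5.0] * 6, [5.0] * 7)
        assert res.U == pytest.approx(21.0)  # n1*n2/2

    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0

    def test_small_sample_matches_bruteforce(self):
        """p for [1,2,3] vs [4,5,6] equals the C(6,3)=20 enumeration."""
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        # only the two complete separations are as extreme: p = 2/20
        assert res.p == pytest.approx(2 / 20)

    def test_scipy_cross_check_large(self, rng):
        a = rng.standard_normal(40)
        b = rng.standard_normal(45) + 0.3
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert res.U == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_u_complement_identity(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(15)
        u_a = mann_whitney(a, b).U
        u_b = mann_whitney(b, a).U
        assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_normal_approx_quality_exhaustive_small_sizes(self):
        """Continuity-corrected normal approximation vs exact enumeration,
        exhaustively over every attainable U for n1+n2 <= 12.

        The worst-case gap of this approximation is .0375 (at n1=n2=3, a
        property of the statistic itself, largest in the smallest designs);
        it tightens as sizes grow.  The default implementation never uses
        the approximation in this regime, so this documents the asymptotic
        path's behaviour rather than user-facing accuracy."""
        import itertools

        for n1 in range(3, 10):
            for n2 in range(3, 13 - n1):
                # tie-free data: exact distribution depends only on ranks
                ranks = np.arange(1.0, n1 + n2 + 1)
                us = np.array([
                    ranks[list(c)].sum() - n1 * (n1 + 1) / 2.0
                    for c in itertools.combinations(range(n1 + n2), n1)
                ])
                mid = n1 * n2 / 2.0
                worst = 0.0
                for u in np.unique(us):
                    p_exact = np.mean(np.abs(us - mid) >= abs(u - mid) - 1e-12)
                    z = (abs(u - mid) - 0.5) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
                    p_approx = min(2 * sps.norm.sf(max(z, 0.0)), 1.0)
                    worst = max(worst, abs(p_exact - p_approx))
                assert worst <= 0.04, (n1, n2, worst)
                if n1 + n2 >= 12:
                    assert worst <= 0.025, (n1, n2, worst)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2, 3])


class TestTypeIError:
    def test_both_tests_hold_level_under_independence(self):
        """Rejection rate at alpha=.05 stays in .05 +/- .01 over 5000 reps."""
        rng = np.random.default_rng(77)
        reps = 5000
        rej_mw = rej_sp = 0
        for _ in range(reps):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            rej_mw += mann_whitney(a, b).significant_at_05
            rej_sp += spearman(a, b).p <= 0.05
        assert abs(rej_mw / reps - 0.05) <= 0.01
        assert abs(rej_sp / reps - 0.05) <= 0.01


class TestSeverity:
    @pytest.mark.parametrize("ahi,binary,ternary", [
        (4.0, "control", "control"),
        (9.99, "control", "control"),
        (10.0, "osa", "mild"),
        (30.0, "osa", "mild"),
        (30.01, "osa", "severe"),
        (45.0, "osa", "severe"),
    ])
    def test_boundaries(self, ahi, binary, ternary):
        assert assign_severity(ahi) == binary
        assert assign_severity(ahi, ternary=True) == ternary

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_severity(-1.0)

    def test_partition_and_refinement(self, female_cohort_frame):
        ahi = female_cohort_frame.ahi.to_numpy()
        b = assign_severity(ahi)
        t = assign_severity(ahi, ternary=True)
        assert set(np.unique(b)) <= {"control", "osa"}
        assert ((b == "control") == (t == "control")).all()
        assert np.isin(t[b == "osa"], ["mild", "severe"]).all()

    def test_invalid_policy(self):
        with pytest.raises(ValueError):
            SeverityPolicy(control_upper=40.0, severe_lower=30.0)


class TestMatchedSubset:
    def test_reference_cohort_age_bmi_filter(self):
        """Age-41-55 / BMI>=25 matching at the study's cohort size:
        AHI separates the groups while the clinical covariates do not."""
        ref = cohort.build_reference_spec("female", features="craniofacial",
                                          n=129, seed=2)
        frame = cohort.cohort_to_frame(cohort.generate_cohort(ref))
        spec = MatchedSubsetSpec(filters={"age": (41.0, 55.0),
                                          "bmi": (25.0, np.inf)})
        control, osa, report = build_matched_subset(frame, spec)
        assert (control.ahi < 10).all() and (osa.ahi >= 10).all()
        by_var = report.set_index("variable")
        assert by_var.loc["ahi", "p"] <= 0.05
        # age was the strongest AHI correlate; the filter must neutralize it
        assert by_var.loc["age", "p"] > 0.05

    def test_exchangeable_null_passes(self, rng):
        n = 400
        df = pd.DataFrame({
            "ahi": np.concatenate([rng.uniform(0, 9.9, n // 2),
                                   rng.uniform(10.1, 60, n // 2)]),
            "age": rng.normal(50, 10, n),
            "bmi": rng.normal(30, 5, n),
            "weight": rng.normal(78, 15, n),
            "height": rng.normal(161, 6, n),
            "cervical_perimeter": rng.normal(36, 3, n),
        })
        _, _, report = build_matched_subset(df, MatchedSubsetSpec())
        assert report.attrs["passed"]

    def test_injected_shift_fails_verification(self, rng):
        n = 400
        ahi = np.concatenate([rng.uniform(0, 9.9, n // 2),
                              rng.uniform(10.1, 60, n // 2)])
        age = np.where(ahi >= 10, rng.normal(60, 5, n), rng.normal(40, 5, n))
        df = pd.DataFrame({
            "ahi": ahi, "age": age,
            "bmi": rng.normal(30, 5, n), "weight": rng.normal(78, 15, n),
            "height": rng.normal(161, 6, n),
            "cervical_perimeter": rng.normal(36, 3, n),
        })
        _, _, report = build_matched_subset(df, MatchedSubsetSpec())
        assert not report.attrs["passed"]
        row = report[report.variable == "age"].iloc[0]
        assert not row.matched_ok
        # independent confirmation of the injected difference
        ref = sps.mannwhitneyu(df[df.ahi < 10].age, df[df.ahi >= 10].age)
        assert ref.pvalue < 0.05

    def test_unknown_filter_variable_rejected(self, female_cohort_frame):
        with pytest.raises(ValueError):
            build_matched_subset(
                female_cohort_frame,
                MatchedSubsetSpec(filters={"shoe_size": (38.0, 42.0)}),
            )


class TestRendering:
    def test_nonsignificant_cell_omitted(self):
        res = stats.CorrelationResult("f", "c", 0.05, 0.6, 100, "ns", "very weak")
        table = render_correlation_table([res])
        assert table.loc["f", "c"] == ""

    def test_empty_results_render_headers(self):
        assert render_contrast_table([]).empty

    def test_deterministic_rendering(self, female_cohort_frame):
        results = correlation_table(female_cohort_frame, ["age"], ["ahi", "bmi"])
        a = render_correlation_table(results).to_csv()
        b = render_correlation_table(results).to_csv()
        assert a == b

    def test_descriptive_table_layout(self, female_cohort_frame):
        t = render_descriptive_table(female_cohort_frame, ["ahi", "age"])
        assert list(t.columns) == ["variable", "mean (sd)", "range", "n"]
        assert t.iloc[0]["n"] == len(female_cohort_frame)
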