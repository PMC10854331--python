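"""Group contrasts, chi-square membership tests, and the functioning model."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_series
from moodinstability.analysis import (
    FunctioningModelSpec,
    ModelSpecError,
    fit_functioning_model,
    instability_group_model,
    threshold_membership_test,
)
from moodinstability.cohort import (
    SyntheticCohortConfig,
    generate_cohort,
    simulate_functioning_from_thresholds,
)
from moodinstability.instability import (
    Category,
    ParticipantThreshold,
    classify_windows,
    participant_threshold,
    percentile_thresholds,
    rolling_variance,
    zscale,
)
from moodinstability.proms import (
    FunctioningRecord,
    Group,
    LongitudinalDataset,
    Participant,
    Race,
    Sex,
)


def hand_chi_square(table):
    """Independent oracle: sum over cells of (O - E)^2 / E with margin-product E."""
    table = np.asarray(table, dtype=float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def _participants(groups, sexes=None, races=None, ages=None):
    out = {}
    for i, g in enumerate(groups):
        pid = f"p{i:03d}"
        out[pid] = Participant(
            pid,
            Group(g),
            Sex(sexes[i]) if sexes else Sex.MALE,
            Race(races[i]) if races else Race.WHITE,
            ages[i] if ages else 40.0,
        )
    return out


def _thresholds_from_counts(counts, participants_by_group):
    """Build a ParticipantThreshold table with given per-group category counts."""
    out = []
    for g, per_cat in counts.items():
        pids = iter(participants_by_group[g])
        for cat, n in per_cat.items():
            for _ in range(n):
                out.append(ParticipantThreshold(next(pids), "PHQ9", 0.0, cat))
    return out


class TestThresholdMembership:
    def _setup(self, counts):
        groups, pbg = [], {}
        for g, per_cat in counts.items():
            n = sum(per_cat.values())
            start = len(groups)
            groups.extend([g] * n)
            pbg[g] = [f"p{i:03d}" for i in range(start, start + n)]
        parts = _participants(groups)
        return parts, _thresholds_from_counts(counts, pbg)

    def test_perfectly_homogeneous_table(self):
        counts = {
            "BD": {Category.HIGH: 10, Category.LOW: 10},
            "HC": {Category.HIGH: 10, Category.LOW: 10},
        }
        parts, th = self._setup(counts)
        res = threshold_membership_test(th, Category.HIGH, parts)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_formula_2x2(self):
        # [[20,10],[10,20]]: all expected cells 15, chi2 = 4 * 25/15 = 6.667
        counts = {
            "BD": {Category.HIGH: 20, Category.LOW: 10},
            "HC": {Category.HIGH: 10, Category.LOW: 20},
        }
        parts, th = self._setup(counts)
        res = threshold_membership_test(th, Category.HIGH, parts)
        assert res.chi_square == pytest.approx(6.667, abs=1e-3)
        assert res.chi_square == pytest.approx(hand_chi_square([[20, 10], [10, 20]]))
        assert res.df == 1

    def test_reference_style_2x3_table_matches_oracle(self):
        """Published low-membership counts: statistic equals the hand formula."""
        counts = {
            "BD": {Category.LOW: 133, Category.MODERATE: 325 - 133},
            "HC": {Category.LOW: 114, Category.MODERATE: 140 - 114},
            "PC": {Category.LOW: 44, Category.MODERATE: 64 - 44},
        }
        parts, th = self._setup(counts)
        res = threshold_membership_test(th, Category.LOW, parts)
        want = hand_chi_square([[133, 192], [114, 26], [44, 20]])
        assert res.chi_square == pytest.approx(want, rel=1e-10)
        assert res.df == 2
        assert len(res.pairwise) == 3

    def test_statistic_invariant_to_group_relabeling(self):
        counts = {
            "BD": {Category.HIGH: 17, Category.LOW: 5},
            "HC": {Category.HIGH: 3, Category.LOW: 25},
        }
        parts, th = self._setup(counts)
        a = threshold_membership_test(th, Category.HIGH, parts)
        flipped = {
            "HC": {Category.HIGH: 17, Category.LOW: 5},
            "BD": {Category.HIGH: 3, Category.LOW: 25},
        }
        parts2, th2 = self._setup(flipped)
        b = threshold_membership_test(th2, Category.HIGH, parts2)
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_absent_category_is_degenerate_not_fatal(self):
        counts = {
            "BD": {Category.LOW: 10},
            "HC": {Category.LOW: 10},
        }
        parts, th = self._setup(counts)
        res = threshold_membership_test(th, Category.HIGH, parts)
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_pairwise_corrected_p_not_smaller(self):
        counts = {
            "BD": {Category.HIGH: 12, Category.LOW: 8},
            "HC": {Category.HIGH: 5, Category.LOW: 15},
            "PC": {Category.HIGH: 7, Category.LOW: 13},
        }
        parts, th = self._setup(counts)
        res = threshold_membership_test(th, Category.HIGH, parts)
        for pw in res.pairwise:
            assert pw.p_value_corrected >= pw.p_value - 1e-12


class TestGroupModel:
    def _null_inputs(self, seed, n=60):
        rng = np.random.default_rng(seed)
        parts, series = {}, []
        for g in ("BD", "PC", "HC"):
            for i in range(n):
                pid = f"{g}{i:03d}"
                parts[pid] = Participant(pid, Group(g), Sex.MALE, Race.WHITE, 40.0)
                s = make_series(rng.gamma(2, 2, size=10), pid)
                series.append(s)
        zscale(series)
        return series, parts

    def test_identical_groups_give_small_effects(self):
        series, parts = self._null_inputs(0, n=100)
        res = instability_group_model(series, parts, "PHQ9")
        assert len(res) == 3
        for c in res:
            assert abs(c.standardized_effect) < 0.1
            assert not c.significant
            assert c.ci_low <= c.estimate <= c.ci_high

    def test_tukey_p_not_smaller_than_unadjusted(self):
        series, parts = self._null_inputs(1)
        for c in instability_group_model(series, parts, "PHQ9"):
            assert c.p_value >= c.p_unadjusted - 1e-12

    def test_single_group_rejected(self):
        rng = np.random.default_rng(2)
        parts = _participants(["HC"] * 5)
        series = [make_series(rng.gamma(2, 2, size=8), p) for p in parts]
        zscale(series)
        with pytest.raises(ModelSpecError):
            instability_group_model(series, parts, "PHQ9")

    def test_zero_between_variance_matches_ols(self):
        """Balanced groups, no participant effect: mixed estimates equal OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        parts, series, rows = {}, [], []
        shift = {"BD": 0.8, "PC": 0.3, "HC": 0.0}
        for g in ("BD", "PC", "HC"):
            for i in range(40):
                pid = f"{g}{i:03d}"
                parts[pid] = Participant(pid, Group(g), Sex.MALE, Race.WHITE, 40.0)
                vals = rng.normal(5.0 + shift[g], 1.0, size=6)
                series.append(make_series(vals, pid))
        zscale(series)
        res = instability_group_model(series, parts, "PHQ9")
        df = pd.DataFrame(
            [
                (parts[s.participant_id].group.value, w.z_value)
                for s in series
                for w in s.windows
            ],
            columns=["group", "z"],
        )
        means = df.groupby("group")["z"].mean()
        for c in res:
            a, b = c.contrast
            assert c.estimate == pytest.approx(means[a] - means[b], abs=1e-6)

    def test_estimates_invariant_to_relabeling_and_order(self):
        series, parts = self._null_inputs(4, n=30)
        res1 = instability_group_model(series, parts, "PHQ9")
        renamed = {f"x_{pid}": Participant(f"x_{pid}", p.group, p.sex, p.race,
                                           p.age_at_enrollment)
                   for pid, p in parts.items()}
        series2 = [
            make_series([w.raw_variance for w in s.windows], f"x_{s.participant_id}")
            for s in reversed(series)
        ]
        zscale(series2)
        res2 = instability_group_model(series2, renamed, "PHQ9")
        for c1, c2 in zip(res1, res2):
            assert c1.estimate == pytest.approx(c2.estimate, abs=1e-8)
            assert c1.p_value == pytest.approx(c2.p_value, abs=1e-8)


def _cohort_with_categories(seed, n_bd=40, n_pc=15, n_hc=20, n_timepoints=21):
    cfg = SyntheticCohortConfig(n_bd=n_bd, n_pc=n_pc, n_hc=n_hc,
                                n_timepoints=n_timepoints, seed=seed)
    ds, _ = generate_cohort(cfg)
    inst = [rolling_variance(s, 6) for s in ds.series_for_scale("PHQ9")]
    inst = [s for s in inst if s.windows]
    zscale(inst)
    th = percentile_thresholds(np.concatenate([s.raw() for s in inst]), "PHQ9")
    for s in inst:
        classify_windows(s, th)
    pts = [t for s in inst if (t := participant_threshold(s, th))]
    return ds, pts


class TestFunctioningModel:
    def test_estimate_schema_and_convergence(self, small_cohort):
        ds, _, _ = small_cohort
        _, pts = _cohort_with_categories(42, 20, 8, 10, 31)
        ds2, pts = _cohort_with_categories(42, 20, 8, 10, 31)
        fit = fit_functioning_model(ds2, pts, FunctioningModelSpec("MCS"))
        assert fit.converged
        assert fit.random_intercept_variance >= 0
        assert fit.residual_variance >= 0
        for term in ("intercept", "bd_vs_hc", "pc_vs_hc", "female_vs_male",
                     "non_white_vs_white", "age_at_enrollment",
                     "moderate_vs_low", "high_vs_low"):
            row = fit.estimates.loc[term]
            assert row.ci_low <= row.estimate <= row.ci_high

    def test_empty_threshold_level_raises_naming_term(self):
        ds, pts = _cohort_with_categories(8)
        pts = [t for t in pts if t.category != Category.HIGH]
        forced = [
            ParticipantThreshold(t.participant_id, t.scale, t.continuous_index,
                                 Category.LOW if t.category == Category.HIGH else t.category)
            for t in pts
        ]
        with pytest.raises(ModelSpecError, match="high"):
            fit_functioning_model(ds, forced, FunctioningModelSpec("MCS"))

    def test_threshold_label_swap_swaps_coefficients(self):
        """Swapping moderate and high labels swaps the corresponding estimates."""
        ds, pts = _cohort_with_categories(9)
        coefs = dict(gamma00=50.0, gamma_bd=-8.0, gamma_pc=-4.0, gamma_sex=0.0,
                     gamma_race=0.0, gamma_age=0.0, gamma_moderate=-3.0, gamma_high=-7.0)
        cats = {t.participant_id: t.category for t in pts}
        ds2 = simulate_functioning_from_thresholds(ds, cats, coefs, 2.0, 3.0, seed=5)
        fit = fit_functioning_model(ds2, pts, FunctioningModelSpec("MCS"))
        swap = {Category.MODERATE: Category.HIGH, Category.HIGH: Category.MODERATE}
        pts_sw = [
            ParticipantThreshold(t.participant_id, t.scale, t.continuous_index,
                                 swap.get(t.category, t.category))
            for t in pts
        ]
        fit_sw = fit_functioning_model(ds2, pts_sw, FunctioningModelSpec("MCS"))
        assert fit_sw.estimates.loc["moderate_vs_low", "estimate"] == pytest.approx(
            fit.estimates.loc["high_vs_low", "estimate"], abs=1e-6
        )
        assert fit_sw.estimates.loc["high_vs_low", "estimate"] == pytest.approx(
            fit.estimates.loc["moderate_vs_low", "estimate"], abs=1e-6
        )

    def test_balanced_design_tiny_intercept_matches_ols(self):
        """With negligible participant variance the fixed effects match OLS."""
        import statsmodels.formula.api as smf

        ds, pts = _cohort_with_categories(10)
        coefs = dict(gamma00=50.0, gamma_bd=-8.0, gamma_pc=-4.0, gamma_sex=-1.0,
                     gamma_race=1.0, gamma_age=0.05, gamma_moderate=-3.0, gamma_high=-7.0)
        cats = {t.participant_id: t.category for t in pts}
        ds2 = simulate_functioning_from_thresholds(ds, cats, coefs, 1e-6, 5.0, seed=6)
        fit = fit_functioning_model(ds2, pts, FunctioningModelSpec("MCS"))
        rows = []
        for pid, recs in ds2.functioning.items():
            p = ds2.participants[pid]
            for r in recs:
                rows.append((r.mcs, p.group.value, p.sex.value, p.race.value,
                             p.age_at_enrollment, cats[pid].label))
        df = pd.DataFrame(rows, columns=["y", "group", "sex", "race", "age", "threshold"])
        ols = smf.ols(
            "y ~ C(group, Treatment('HC')) + C(sex, Treatment('male')) "
            "+ C(race, Treatment('white')) + age + C(threshold, Treatment('low'))",
            df,
        ).fit()
        assert fit.estimates.loc["bd_vs_hc", "estimate"] == pytest.approx(
            ols.params["C(group, Treatment('HC'))[T.BD]"], abs=1e-4
        )
        assert fit.estimates.loc["high_vs_low", "estimate"] == pytest.approx(
            ols.params["C(threshold, Treatment('low'))[T.high]"], abs=1e-4
        )

    def test_null_outcome_rarely_significant(self):
        """Pure-noise outcomes produce no significant fixed effects at alpha 0.001."""
        bad = 0
        for rep in range(5):
            ds, pts = _cohort_with_categories(300 + rep)
            coefs = dict(gamma00=50.0, gamma_bd=0.0, gamma_pc=0.0, gamma_sex=0.0,
                         gamma_race=0.0, gamma_age=0.0, gamma_moderate=0.0, gamma_high=0.0)
            cats = {t.participant_id: t.category for t in pts}
            ds2 = simulate_functioning_from_thresholds(ds, cats, coefs, 6.0, 8.0,
                                                       seed=400 + rep)
            fit = fit_functioning_model(ds2, pts, FunctioningModelSpec("MCS"))
            terms = fit.estimates.drop("intercept")
            bad += bool(terms["significant"].any())
        assert bad <= 1
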