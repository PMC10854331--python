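"""Inferential stage: group contrasts, threshold-membership tests, functioning models.

Three analyses sit downstream of the instability pipeline:

1. ``instability_group_model`` — a random-intercept linear mixed model of the
   z-scaled instability index on diagnostic group, with all pairwise group
   contrasts Tukey-adjusted (studentized-range distribution) and standardized
   by the total outcome SD, sqrt(sigma2_intercept + sigma2_residual).
2. ``threshold_membership_test`` — Pearson chi-square tests of category
   membership (in-category vs not) across groups, omnibus plus all pairwise
   2x2 tests (reported with and without continuity correction).
3. ``fit_functioning_model`` — the SF-12 functioning model: outcome T-score
   on diagnostic group (reference HC), sex (reference male), race (reference
   white), age at enrollment, and instability threshold entered as
   moderate-vs-low and high-vs-low indicators, with a participant random
   intercept, fitted by REML.

The alpha level is 0.001 throughout, compensating for the large number of
within-person observations.  Because every fixed effect in these models is a
between-person quantity, p-values and intervals use a t reference with
between-cluster degrees of freedom (participants minus fixed effects).
"Robust to missingness" means observation-level complete-case likelihood,
the standard mixed-model behavior, not imputation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .instability import Category, InstabilitySeries, ParticipantThreshold
from .proms import Group, LongitudinalDataset, Participant, Race, Sex

__all__ = [
    "ALPHA",
    "GroupContrastResult",
    "PairwiseChiSquare",
    "ThresholdMembershipTest",
    "FunctioningModelSpec",
    "FunctioningModelFit",
    "ModelSpecError",
    "instability_group_model",
    "threshold_membership_test",
    "fit_functioning_model",
]

logger = logging.getLogger(__name__)

ALPHA = 0.001

_GROUP_ORDER = ["BD", "PC", "HC"]
_CONTRASTS = [("BD", "HC"), ("BD", "PC"), ("PC", "HC")]


class ModelSpecError(ValueError):
    """The design is rank-deficient or a required factor level is absent."""


@dataclass(frozen=True)
class GroupContrastResult:
    scale: str
    contrast: tuple[str, str]
    estimate: float  # difference in model-implied means, z-instability units
    standardized_effect: float  # estimate / sqrt(var_intercept + var_residual)
    ci_low: float
    ci_high: float
    p_value: float  # Tukey-adjusted
    p_unadjusted: float
    significant: bool  # at alpha = 0.001


@dataclass(frozen=True)
class PairwiseChiSquare:
    groups: tuple[str, str]
    chi_square: float
    chi_square_corrected: float
    df: int
    p_value: float
    p_value_corrected: float


@dataclass
class ThresholdMembershipTest:
    scale: str
    category: Category
    counts: pd.DataFrame  # groups x {in_category, not_in_category}
    expected: np.ndarray
    chi_square: float
    df: int
    p_value: float
    pairwise: list[PairwiseChiSquare]
    small_expected_warning: bool
    significant: bool


@dataclass(frozen=True)
class FunctioningModelSpec:
    """Fixed-effect layout of the functioning model; reference levels are fixed."""

    outcome: str = "MCS"  # or "PCS"
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if self.outcome not in ("MCS", "PCS"):
            raise ValueError("outcome must be MCS or PCS")


@dataclass
class FunctioningModelFit:
    outcome: str
    estimates: pd.DataFrame  # term -> estimate, ci_low, ci_high, p_value, significant
    random_intercept_variance: float
    residual_variance: float
    n_observations: int
    n_participants: int
    converged: bool


def _chi_square_homogeneity(table: np.ndarray) -> tuple[float, int, float, np.ndarray]:
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p), expected


def _tukey_p(t_stat: float, k: int, df: float) -> float:
    """Tukey-adjusted p for a pairwise contrast among k means (Tukey-Kramer)."""
    q = abs(t_stat) * np.sqrt(2.0)
    return float(stats.studentized_range.sf(q, k, df))


def instability_group_model(
    windows: Sequence[InstabilitySeries],
    participants: dict[str, Participant],
    scale: str,
    alpha: float = ALPHA,
) -> list[GroupContrastResult]:
    """Mixed model of z-scaled instability on diagnostic group, pairwise contrasts.

    Fits ``z_value ~ group`` with a participant random intercept by REML and
    returns BD-HC, BD-PC and PC-HC contrasts with Tukey-adjusted p-values,
    Tukey-adjusted 95% intervals, and d-type standardized effects (contrast
    divided by the total outcome SD).  Non-convergence raises with the fit
    diagnostics rather than silently falling back.
    """
    rows = []
    for s in windows:
        if s.scale != scale:
            continue
        g = participants[s.participant_id].group.value
        for w in s.windows:
            if w.z_value is None:
                raise ValueError("windows must be z-scaled before instability_group_model")
            rows.append((s.participant_id, g, w.z_value))
    df = pd.DataFrame(rows, columns=["participant_id", "group", "z"])
    present = [g for g in _GROUP_ORDER if g in set(df["group"])]
    if len(present) < 2:
        raise ModelSpecError(f"need >= 2 diagnostic groups, found {present}")
    for g in present:
        if df.loc[df.group == g, "participant_id"].nunique() < 2:
            raise ModelSpecError(f"group {g} has < 2 participants")

    model = smf.mixedlm("z ~ C(group, Treatment('HC'))" if "HC" in present
                        else "z ~ C(group)", df, groups=df["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    if not fit.converged:
        raise RuntimeError(f"mixed model did not converge: {fit.summary()}")

    var_u = float(fit.cov_re.iloc[0, 0])
    var_e = float(fit.scale)
    total_sd = np.sqrt(var_u + var_e)
    k = len(present)
    n_participants = df["participant_id"].nunique()
    ddf = max(n_participants - k, 2)

    # model-implied group means via the fixed-effect design
    names = list(fit.fe_params.index)
    beta = fit.fe_params.values
    cov = fit.cov_params().loc[names, names].values

    def mean_vector(group: str) -> np.ndarray:
        v = np.zeros(len(names))
        for j, name in enumerate(names):
            if name == "Intercept":
                v[j] = 1.0
            elif f"[T.{group}]" in name:
                v[j] = 1.0
        return v

    results = []
    q_crit = stats.studentized_range.ppf(0.95, k, ddf)
    for a, b in _CONTRASTS:
        if a not in present or b not in present:
            continue
        c = mean_vector(a) - mean_vector(b)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        t = est / se if se > 0 else np.inf
        p_adj = _tukey_p(t, k, ddf)
        p_raw = float(2 * stats.t.sf(abs(t), ddf))
        half = q_crit / np.sqrt(2.0) * se
        results.append(
            GroupContrastResult(
                scale=scale,
                contrast=(a, b),
                estimate=est,
                standardized_effect=est / total_sd,
                ci_low=est - half,
                ci_high=est + half,
                p_value=p_adj,
                p_unadjusted=p_raw,
                significant=p_adj < alpha,
            )
        )
    return results


def threshold_membership_test(
    thresholds: Sequence[ParticipantThreshold],
    category: Category,
    participants: dict[str, Participant],
    alpha: float = ALPHA,
) -> ThresholdMembershipTest:
    """Chi-square homogeneity of category membership across diagnostic groups.

    Builds the groups x {in-category, not-in-category} table from the
    participant-level thresholds, computes the omnibus Pearson chi-square
    (no continuity correction, df = G-1) plus every pairwise 2x2 test
    (both with and without Yates correction).  A category held by no
    participant in any group yields a degenerate result (chi-square 0) with
    a warning rather than an error.
    """
    if not thresholds:
        raise ValueError("empty threshold table")
    scale = thresholds[0].scale
    groups_present = sorted(
        {participants[t.participant_id].group.value for t in thresholds},
        key=_GROUP_ORDER.index,
    )
    if len(groups_present) < 2:
        raise ModelSpecError("need >= 2 diagnostic groups")
    counts = pd.DataFrame(
        0, index=groups_present, columns=["in_category", "not_in_category"]
    )
    for t in thresholds:
        g = participants[t.participant_id].group.value
        col = "in_category" if t.category == category else "not_in_category"
        counts.loc[g, col] += 1

    table = counts.values
    if counts["in_category"].sum() == 0 or counts["not_in_category"].sum() == 0:
        logger.warning(
            "threshold_membership_test: category %s degenerate (one column empty)",
            category.label,
        )
        expected = table.astype(float)
        chi2, df_, p = 0.0, len(groups_present) - 1, 1.0
    else:
        chi2, df_, p, expected = _chi_square_homogeneity(table)

    pairwise = []
    for a, b in itertools.combinations(groups_present, 2):
        sub = counts.loc[[a, b]].values
        if sub[:, 0].sum() == 0 or sub[:, 1].sum() == 0:
            pairwise.append(PairwiseChiSquare((a, b), 0.0, 0.0, 1, 1.0, 1.0))
            continue
        c_u, _, p_u, _ = stats.chi2_contingency(sub, correction=False)
        c_c, _, p_c, _ = stats.chi2_contingency(sub, correction=True)
        pairwise.append(
            PairwiseChiSquare((a, b), float(c_u), float(c_c), 1, float(p_u), float(p_c))
        )

    small = bool((expected < 5).any())
    if small:
        logger.warning("threshold_membership_test: expected cell count < 5 present")
    return ThresholdMembershipTest(
        scale=scale,
        category=category,
        counts=counts,
        expected=np.asarray(expected, dtype=float),
        chi_square=chi2,
        df=df_,
        p_value=p,
        pairwise=pairwise,
        small_expected_warning=small,
        significant=p < alpha,
    )


def fit_functioning_model(
    ds: LongitudinalDataset,
    thresholds: Sequence[ParticipantThreshold],
    spec: FunctioningModelSpec = FunctioningModelSpec(),
) -> FunctioningModelFit:
    """REML random-intercept model of SF-12 functioning on covariates + threshold.

    The participant-level instability category is broadcast to all of that
    participant's functioning observations and entered as moderate-vs-low and
    high-vs-low indicators.  Estimates are in T-score units.  Observations
    with a missing outcome are dropped (complete-case likelihood).  An empty
    threshold level or absent factor level raises :class:`ModelSpecError`
    naming the aliased term.
    """
    cat_by_pid = {t.participant_id: t.category.label for t in thresholds}
    rows = []
    for pid, recs in ds.functioning.items():
        if pid not in cat_by_pid:
            continue
        p = ds.participants[pid]
        for r in recs:
            y = r.mcs if spec.outcome == "MCS" else r.pcs
            if y is None or not np.isfinite(y):
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "y": y,
                    "group": p.group.value,
                    "sex": p.sex.value,
                    "race": p.race.value,
                    "age": p.age_at_enrollment,
                    "threshold": cat_by_pid[pid],
                }
            )
    df = pd.DataFrame(rows)
    if len(df) < 50:
        raise ValueError(f"need >= 50 functioning observations, got {len(df)}")

    for col, levels, ref in (
        ("group", ["BD", "PC", "HC"], "HC"),
        ("threshold", ["low", "moderate", "high"], "low"),
    ):
        present = set(df[col])
        missing = [l for l in levels if l not in present]
        if missing:
            raise ModelSpecError(
                f"factor {col!r} level(s) {missing} empty: term would be aliased"
            )

    formula = (
        "y ~ C(group, Treatment('HC')) + C(sex, Treatment('male')) "
        "+ C(race, Treatment('white')) + age "
        "+ C(threshold, Treatment('low'))"
    )
    model = smf.mixedlm(formula, df, groups=df["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)

    rename = {
        "Intercept": "intercept",
        "C(group, Treatment('HC'))[T.BD]": "bd_vs_hc",
        "C(group, Treatment('HC'))[T.PC]": "pc_vs_hc",
        "C(sex, Treatment('male'))[T.female]": "female_vs_male",
        "C(race, Treatment('white'))[T.non_white]": "non_white_vs_white",
        "age": "age_at_enrollment",
        "C(threshold, Treatment('low'))[T.moderate]": "moderate_vs_low",
        "C(threshold, Treatment('low'))[T.high]": "high_vs_low",
    }
    # all fixed effects are between-person, so inference uses a t reference
    # with between-cluster df (participants minus fixed effects) rather than
    # the asymptotic normal; at a few hundred participants the difference is
    # small but the t calibrates small-cohort coverage correctly
    n_participants = df["participant_id"].nunique()
    ddf = max(n_participants - len(fit.fe_params), 2)
    tcrit = stats.t.ppf(0.975, ddf)
    records = []
    for raw_name, name in rename.items():
        if raw_name not in fit.fe_params.index:
            continue
        est = float(fit.fe_params[raw_name])
        se = float(fit.bse_fe[raw_name])
        pv = float(2 * stats.t.sf(abs(est / se), ddf)) if se > 0 else 0.0
        records.append(
            {
                "term": name,
                "estimate": est,
                "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se,
                "p_value": pv,
                "significant": pv < spec.alpha,
            }
        )
    est_df = pd.DataFrame(records).set_index("term")
    return FunctioningModelFit(
        outcome=spec.outcome,
        estimates=est_df,
        random_intercept_variance=float(fit.cov_re.iloc[0, 0]),
        residual_variance=float(fit.scale),
        n_observations=len(df),
        n_participants=n_participants,
        converged=bool(fit.converged),
    )
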