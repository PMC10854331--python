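"""Seeded generator of synthetic longitudinal PROM cohorts with known ground truth.

The real data this package was designed around — a decade-plus bipolar
cohort assessed every two months, available only under a Data Use Agreement —
cannot ship with the code.  This module generates cohorts with the same
statistical skeleton so every pipeline stage is testable end to end:

* three diagnostic groups (bipolar disorder BD, psychiatric comparison PC,
  healthy control HC) with group-ordered within-person variance (BD > PC > HC),
* bounded ordinal scale scores produced by rounding and clipping a latent
  AR(1) trajectory plus episodic square-wave mood shifts,
* missing-completely-at-random assessment gaps (an optional mood-dependent
  mode for sensitivity work),
* SF-12 MCS/PCS T-scores from a random-intercept linear model whose
  instability term is the participant's true (standardized log) innovation
  scale, so recovery of generating coefficients can be checked.

Mood dynamics are deliberately not a clinical episode simulator; an AR(1)
process with square-wave shifts is sufficient to induce the variance ordering
the downstream analyses exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .proms import (
    FunctioningRecord,
    Group,
    LongitudinalDataset,
    Participant,
    PromSeries,
    Race,
    SCALES,
    Sex,
)

__all__ = [
    "ScaleGenParams",
    "OutcomeCoefficients",
    "SyntheticCohortConfig",
    "GroundTruth",
    "generate_cohort",
    "study_shaped_preset",
    "simulate_functioning_from_thresholds",
]


@dataclass(frozen=True)
class ScaleGenParams:
    """Latent-trajectory parameters for one scale."""

    baseline_mean: float
    between_sd: float  # SD of person-level means
    innovation_sd: float  # base AR(1) innovation SD (before group multiplier)


@dataclass(frozen=True)
class OutcomeCoefficients:
    """Fixed effects of the functioning (SF-12 T-score) generating model.

    gamma_instability multiplies the participant's standardized log innovation
    scale — the latent quantity the pipeline's continuous instability index
    estimates.
    """

    gamma00: float
    gamma_bd: float
    gamma_pc: float
    gamma_sex: float  # female vs male
    gamma_race: float  # non-white vs white
    gamma_age: float  # per year of age at enrollment
    gamma_instability: float


@dataclass
class SyntheticCohortConfig:
    """All generator knobs; defaults are the study-like conditions.

    61 scheduled timepoints is ten years of bi-monthly assessments including
    baseline.  Innovation multipliers 2.0 / 1.3 / 1.0 (BD / PC / HC) give BD
    four times the within-person innovation variance of controls, producing
    the group ordering of instability the analyses test for.  Episodes occur
    in the BD group at ~0.5/year with amplitude 8 latent score points,
    emulating the occasional syndromal excursions on top of subsyndromal
    fluctuation.
    """

    n_bd: int = 60
    n_pc: int = 20
    n_hc: int = 30
    n_timepoints: int = 61
    scales: dict[str, ScaleGenParams] = field(
        default_factory=lambda: {
            "PHQ9": ScaleGenParams(6.0, 4.0, 2.5),
            "ASRM": ScaleGenParams(7.0, 2.0, 1.8),
            "GAD7": ScaleGenParams(5.0, 3.0, 2.2),
        }
    )
    ar_coefficient: float = 0.3
    innovation_sd_multipliers: dict[str, float] = field(
        default_factory=lambda: {"BD": 2.0, "PC": 1.3, "HC": 1.0}
    )
    frailty_log_sd: float = 0.3  # person-level lognormal spread of innovation scale
    episode_rate_bd: float = 0.5  # expected episodes per BD participant per year
    episode_amplitude: float = 8.0
    episode_mean_duration: float = 2.0  # assessments (geometric)
    missing_rate: float = 0.15
    mnar_mood_dependence: float = 0.0  # optional: extra missingness per latent score point
    mcs_coefficients: OutcomeCoefficients = field(
        default_factory=lambda: OutcomeCoefficients(52.0, -12.0, -6.0, -0.5, 0.5, 0.08, -3.0)
    )
    pcs_coefficients: OutcomeCoefficients = field(
        default_factory=lambda: OutcomeCoefficients(55.0, -6.0, -3.0, -1.0, -0.5, -0.2, 1.0)
    )
    random_intercept_sd: float = 6.0
    residual_sd: float = 8.0
    seed: int = 2024

    def __post_init__(self) -> None:
        if min(self.n_bd, self.n_pc, self.n_hc) < 0:
            raise ValueError("group sizes must be >= 0")
        if not -1 < self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in (-1, 1)")
        if any(m <= 0 for m in self.innovation_sd_multipliers.values()):
            raise ValueError("innovation multipliers must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.random_intercept_sd <= 0 or self.residual_sd <= 0:
            raise ValueError("random_intercept_sd and residual_sd must be > 0")


@dataclass
class GroundTruth:
    """Latent quantities stored alongside a generated dataset for recovery tests."""

    innovation_scale: dict[str, float]  # participant -> lognormal frailty multiplier
    latent_instability: dict[str, float]  # standardized log innovation scale
    random_intercepts: dict[str, float]
    episode_windows: dict[str, list[tuple[int, int]]]  # participant -> (start, end) inclusive
    mcs_coefficients: OutcomeCoefficients = None
    pcs_coefficients: OutcomeCoefficients = None

    def to_dict(self) -> dict:
        return {
            "innovation_scale": self.innovation_scale,
            "latent_instability": self.latent_instability,
            "random_intercepts": self.random_intercepts,
            "episode_windows": {k: [list(w) for w in v] for k, v in self.episode_windows.items()},
            "mcs_coefficients": asdict(self.mcs_coefficients),
            "pcs_coefficients": asdict(self.pcs_coefficients),
        }


def _stationary_ar1(rng: np.random.Generator, n: int, phi: float, innov_sd: float) -> np.ndarray:
    e = np.empty(n)
    e[0] = rng.normal(0.0, innov_sd / np.sqrt(1.0 - phi**2))
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + shocks[t - 1]
    return e


def generate_cohort(config: SyntheticCohortConfig) -> tuple[LongitudinalDataset, GroundTruth]:
    """Generate a cohort dataset and its ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    participants: dict[str, Participant] = {}
    order: list[tuple[str, Group]] = []
    for group, n in ((Group.BD, config.n_bd), (Group.PC, config.n_pc), (Group.HC, config.n_hc)):
        for i in range(n):
            pid = f"{group.value}{i:04d}"
            order.append((pid, group))

    frailty: dict[str, float] = {}
    intercepts: dict[str, float] = {}
    episodes: dict[str, list[tuple[int, int]]] = {}
    years = (config.n_timepoints - 1) / 6.0  # 6 assessments per year after baseline

    for pid, group in order:
        sex = Sex.FEMALE if rng.random() < 0.657 else Sex.MALE
        race = Race.NON_WHITE if rng.random() < 0.214 else Race.WHITE
        age = float(np.clip(rng.normal(39.0, 14.0), 18.0, 85.0))
        participants[pid] = Participant(pid, group, sex, race, age)
        frailty[pid] = float(np.exp(rng.normal(0.0, config.frailty_log_sd)))
        intercepts[pid] = float(rng.normal(0.0, config.random_intercept_sd))
        ep: list[tuple[int, int]] = []
        if group is Group.BD and config.episode_rate_bd > 0:
            n_ep = rng.poisson(config.episode_rate_bd * years)
            for _ in range(n_ep):
                start = int(rng.integers(0, config.n_timepoints))
                dur = int(rng.geometric(1.0 / config.episode_mean_duration))
                ep.append((start, min(start + dur - 1, config.n_timepoints - 1)))
        episodes[pid] = ep

    # standardized log innovation scale: the latent the continuous index estimates
    log_scale = {
        pid: np.log(frailty[pid] * config.innovation_sd_multipliers[g.value])
        for pid, g in order
    }
    ls = np.array(list(log_scale.values()))
    if len(ls) == 0:
        latent = {}
    else:
        ls_mean = float(ls.mean())
        ls_sd = float(ls.std(ddof=1)) if len(ls) > 1 else 1.0
        latent = {pid: (v - ls_mean) / (ls_sd if ls_sd > 0 else 1.0) for pid, v in log_scale.items()}

    series: dict[tuple[str, str], PromSeries] = {}
    functioning: dict[str, list[FunctioningRecord]] = {}
    T = config.n_timepoints

    for pid, group in order:
        mult = config.innovation_sd_multipliers[group.value] * frailty[pid]
        ep_mask = np.zeros(T)
        ep_types = []
        for start, end in episodes[pid]:
            ep_types.append("manic" if rng.random() < 0.5 else "depressive")
        for scale_name, params in config.scales.items():
            sdef = SCALES[scale_name]
            mu = params.baseline_mean + rng.normal(0.0, params.between_sd)
            shift = np.zeros(T)
            for (start, end), etype in zip(episodes[pid], ep_types):
                amp = config.episode_amplitude
                if etype == "depressive" and scale_name == "PHQ9":
                    shift[start : end + 1] += amp
                elif etype == "depressive" and scale_name == "GAD7":
                    shift[start : end + 1] += amp / 2.0
                elif etype == "manic" and scale_name == "ASRM":
                    shift[start : end + 1] += amp * 0.6
            e = _stationary_ar1(rng, T, config.ar_coefficient, params.innovation_sd * mult)
            x = mu + shift + e
            scores = np.clip(np.round(x), sdef.min_score, sdef.max_score).astype(int)
            miss_p = np.full(T, config.missing_rate)
            if config.mnar_mood_dependence > 0:
                miss_p = np.clip(
                    miss_p + config.mnar_mood_dependence * (x - mu), 0.0, 0.95
                )
            missing = rng.random(T) < miss_p
            obs = [(t, None if missing[t] else int(scores[t])) for t in range(T)]
            series[(pid, scale_name)] = PromSeries(pid, scale_name, obs)

        p = participants[pid]
        recs = []
        for t in range(T):
            row = []
            for coef in (config.mcs_coefficients, config.pcs_coefficients):
                y = (
                    coef.gamma00
                    + coef.gamma_bd * (group is Group.BD)
                    + coef.gamma_pc * (group is Group.PC)
                    + coef.gamma_sex * (p.sex is Sex.FEMALE)
                    + coef.gamma_race * (p.race is Race.NON_WHITE)
                    + coef.gamma_age * p.age_at_enrollment
                    + coef.gamma_instability * latent[pid]
                    + intercepts[pid]
                    + rng.normal(0.0, config.residual_sd)
                )
                row.append(float(y))
            recs.append(FunctioningRecord(pid, t, row[0], row[1]))
        functioning[pid] = recs

    ds = LongitudinalDataset(participants, series, functioning)
    truth = GroundTruth(
        innovation_scale=frailty,
        latent_instability=latent,
        random_intercepts=intercepts,
        episode_windows=episodes,
        mcs_coefficients=config.mcs_coefficients,
        pcs_coefficients=config.pcs_coefficients,
    )
    return ds, truth


def study_shaped_preset(seed: int = 2024) -> SyntheticCohortConfig:
    """Config shaped like the study cohort: 385 BD / 71 PC / 147 HC, 61 timepoints.

    Group sizes and cadence mirror the published cohort design; every other
    value (variance multipliers, episode process, missingness, outcome
    coefficients) is a calibration choice of this generator, not a fact about
    the real data.
    """
    return SyntheticCohortConfig(n_bd=385, n_pc=71, n_hc=147, n_timepoints=61, seed=seed)


def simulate_functioning_from_thresholds(
    ds: LongitudinalDataset,
    categories: dict[str, "object"],
    coefficients: dict[str, float],
    random_intercept_sd: float = 6.0,
    residual_sd: float = 8.0,
    seed: int = 0,
) -> LongitudinalDataset:
    """Regenerate MCS/PCS from threshold-category indicators with known coefficients.

    ``categories`` maps participant_id to a :class:`~.instability.Category`
    (or its lowercase label).  ``coefficients`` must provide ``gamma00``,
    ``gamma_bd``, ``gamma_pc``, ``gamma_sex``, ``gamma_race``, ``gamma_age``,
    ``gamma_moderate`` and ``gamma_high`` — the indicator contrasts of the
    functioning model.  Returns a new dataset sharing participants and PROM
    series with ``ds`` but with freshly simulated functioning records, so
    parameter recovery of the fitted model can be checked against truth.
    """
    rng = np.random.default_rng(seed)
    intercepts = {pid: rng.normal(0.0, random_intercept_sd) for pid in sorted(ds.participants)}
    functioning: dict[str, list[FunctioningRecord]] = {}
    n_t = max(
        (obs[-1][0] + 1 for s in ds.series.values() if (obs := s.observations)),
        default=0,
    )
    for pid in sorted(ds.participants):
        if pid not in categories:
            continue
        p = ds.participants[pid]
        cat = categories[pid]
        label = getattr(cat, "label", str(cat))
        recs = []
        for t in range(n_t):
            mean = (
                coefficients["gamma00"]
                + coefficients["gamma_bd"] * (p.group is Group.BD)
                + coefficients["gamma_pc"] * (p.group is Group.PC)
                + coefficients["gamma_sex"] * (p.sex is Sex.FEMALE)
                + coefficients["gamma_race"] * (p.race is Race.NON_WHITE)
                + coefficients["gamma_age"] * p.age_at_enrollment
                + coefficients["gamma_moderate"] * (label == "moderate")
                + coefficients["gamma_high"] * (label == "high")
                + intercepts[pid]
            )
            recs.append(
                FunctioningRecord(
                    pid, t, float(mean + rng.normal(0.0, residual_sd)),
                    float(mean + rng.normal(0.0, residual_sd)),
                )
            )
        functioning[pid] = recs
    return LongitudinalDataset(dict(ds.participants), dict(ds.series), functioning)
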