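"""Mood-instability indices from rolling within-person variance.

The central quantity is the rolling sample variance of a participant's PROM
scores over a trailing window of k consecutive non-missing bi-monthly
assessments (k = 3, 6, 12 ~ six months, one year, two years).  Raw rolling
variances are pooled across all participants for a scale, z-scaled into a
continuous instability index, and cut at the ranked 60th / 95th percentiles
into low / moderate / high instability categories.  Window-width diagnostics
(LOESS mean squared error and raw-series SD) support re-deriving the choice
of k on new data; the default is k = 6, the one-year window.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .proms import PromSeries, SCALES, ValidationError

__all__ = [
    "Category",
    "InstabilityWindow",
    "InstabilitySeries",
    "WindowDiagnostics",
    "ThresholdSet",
    "ParticipantThreshold",
    "DegenerateDistributionError",
    "InsufficientDataError",
    "rolling_variance",
    "window_diagnostics",
    "select_window",
    "zscale",
    "percentile_thresholds",
    "classify_windows",
    "participant_threshold",
]

logger = logging.getLogger(__name__)

CANDIDATE_WIDTHS = (3, 6, 12)
DEFAULT_WIDTH = 6  # one year of bi-monthly assessments
DEFAULT_LOESS_SPAN = 0.75
LOW_PERCENTILE = 60
HIGH_PERCENTILE = 95
MAX_SPAN_FACTOR = 1.5


class Category(enum.IntEnum):
    """Instability stratum; ordering low < moderate < high is meaningful."""

    LOW = 0
    MODERATE = 1
    HIGH = 2

    @property
    def label(self) -> str:
        return self.name.lower()


class DegenerateDistributionError(ValueError):
    """Pooled values have zero spread where spread is required."""


class InsufficientDataError(ValueError):
    """Too few pooled values for a stable empirical percentile table."""


@dataclass
class InstabilityWindow:
    end_time_index: int
    raw_variance: float
    z_value: Optional[float] = None
    category: Optional[Category] = None


@dataclass
class InstabilitySeries:
    """Rolling-variance windows derived from one participant x scale series."""

    participant_id: str
    scale: str
    window_width_k: int
    windows: list[InstabilityWindow] = field(default_factory=list)

    def raw(self) -> np.ndarray:
        return np.array([w.raw_variance for w in self.windows], dtype=float)


@dataclass(frozen=True)
class WindowDiagnostics:
    """Across-participant mean LOESS MSE and raw-series SD for one window width."""

    window_width_k: int
    mse: float
    sd: float


@dataclass
class ThresholdSet:
    """Ranked-percentile table of pooled raw variances with the 60/95 cutoffs."""

    scale: str
    percentile_values: np.ndarray  # entry p-1 is the p-th ranked percentile, p = 1..100
    low_cutoff: float
    high_cutoff: float
    convention: str = "inverted_cdf"
    n_pooled: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scale": self.scale,
            "convention": self.convention,
            "n_pooled": self.n_pooled,
            "low_percentile": LOW_PERCENTILE,
            "high_percentile": HIGH_PERCENTILE,
            "low_cutoff": self.low_cutoff,
            "high_cutoff": self.high_cutoff,
            "percentile_values": [float(v) for v in self.percentile_values],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        d = json.loads(Path(path).read_text())
        return cls(
            scale=d["scale"],
            percentile_values=np.array(d["percentile_values"], dtype=float),
            low_cutoff=d["low_cutoff"],
            high_cutoff=d["high_cutoff"],
            convention=d["convention"],
            n_pooled=d["n_pooled"],
        )


@dataclass
class ParticipantThreshold:
    participant_id: str
    scale: str
    continuous_index: float
    category: Category


def rolling_variance(
    series: PromSeries,
    window_width_k: int = DEFAULT_WIDTH,
    max_span_factor: float = MAX_SPAN_FACTOR,
) -> InstabilitySeries:
    """Trailing rolling sample variance over k consecutive non-missing scores.

    Each window covers the k most recent non-missing observations and is
    accepted only if its time_index span is at most ``max_span_factor * (k-1)``
    scheduled intervals — a window stretched by long gaps no longer represents
    the nominal calendar duration and is skipped.  The variance is the
    unbiased sample variance (denominator k-1).  Participants with fewer than
    k usable observations yield an empty series.
    """
    if window_width_k < 2:
        raise ValueError("window_width_k must be >= 2")
    if series.scale not in SCALES:
        raise ValidationError(f"unknown scale {series.scale!r}")
    obs = series.non_missing()
    out = InstabilitySeries(series.participant_id, series.scale, window_width_k)
    if len(obs) < window_width_k:
        return out
    times = np.array([t for t, _ in obs])
    scores = np.array([s for _, s in obs], dtype=float)
    max_span = max_span_factor * (window_width_k - 1)
    for i in range(window_width_k - 1, len(obs)):
        lo = i - window_width_k + 1
        if times[i] - times[lo] > max_span:
            continue
        v = float(np.var(scores[lo : i + 1], ddof=1))
        out.windows.append(InstabilityWindow(int(times[i]), v))
    return out


def window_diagnostics(
    series_set: Iterable[InstabilitySeries],
    loess_span: float = DEFAULT_LOESS_SPAN,
) -> list[WindowDiagnostics]:
    """LOESS responsiveness diagnostics per candidate window width.

    For each width present in ``series_set``, fits a LOESS smooth to every
    participant's raw rolling-variance sequence against its window end index,
    then averages across participants (a) the mean squared error between raw
    and smoothed values and (b) the SD of the raw values.  Participants with
    fewer than 5 windows cannot be smoothed and are excluded with a warning.
    A small MSE with a large SD marks a width that tracks real fluctuation
    rather than noise.
    """
    if not 0 < loess_span <= 1:
        raise ValueError("loess_span must be in (0, 1]")
    by_width: dict[int, list[InstabilitySeries]] = {}
    for s in series_set:
        by_width.setdefault(s.window_width_k, []).append(s)
    out = []
    for k in sorted(by_width):
        mses, sds = [], []
        for s in by_width[k]:
            raw = s.raw()
            if len(raw) < 5:
                logger.warning(
                    "window_diagnostics: %s/%s has %d < 5 windows at k=%d; excluded",
                    s.participant_id, s.scale, len(raw), k,
                )
                continue
            x = np.array([w.end_time_index for w in s.windows], dtype=float)
            smooth = lowess(raw, x, frac=loess_span, return_sorted=False)
            mses.append(float(np.mean((raw - smooth) ** 2)))
            sds.append(float(np.std(raw, ddof=1)))
        if not mses:
            logger.warning("window_diagnostics: no usable participants at k=%d", k)
            continue
        out.append(WindowDiagnostics(k, float(np.mean(mses)), float(np.mean(sds))))
    return out


def select_window(diagnostics: Sequence[WindowDiagnostics]) -> int:
    """Pick the window width with lowest MSE but highest SD.

    The verbal criterion is made total by ranking widths ascending on MSE and
    descending on SD and minimizing the rank sum; ties go to the smaller
    width (logged).
    """
    if len(diagnostics) < 2:
        raise ValueError("need diagnostics for at least 2 window widths")
    diags = list(diagnostics)
    # competition ranks: equal criteria get equal rank, so exact ties surface
    score = {
        d.window_width_k: sum(o.mse < d.mse for o in diags)
        + sum(o.sd > d.sd for o in diags)
        for d in diags
    }
    best = min(score.values())
    winners = sorted(k for k, v in score.items() if v == best)
    if len(winners) > 1:
        logger.warning("select_window: tie among widths %s; choosing %d", winners, winners[0])
    return winners[0]


def zscale(pooled: Sequence[InstabilitySeries]) -> list[InstabilitySeries]:
    """Z-scale raw rolling variances against the pooled distribution of a scale.

    All windows of all participants for the scale form the pooling universe;
    each window's ``z_value`` becomes (raw - pooled mean) / pooled sample SD,
    so the pooled z-values have mean 0 and sample SD 1.  Mutates and returns
    the input series.
    """
    scales = {s.scale for s in pooled}
    if len(scales) > 1:
        raise ValidationError(f"zscale pools one scale at a time, got {sorted(scales)}")
    values = np.concatenate([s.raw() for s in pooled]) if pooled else np.array([])
    if len(values) < 2:
        raise ValueError("need >= 2 pooled windows to z-scale")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        raise DegenerateDistributionError("pooled raw variances are all identical")
    for s in pooled:
        for w in s.windows:
            w.z_value = (w.raw_variance - mean) / sd
    return list(pooled)


def percentile_thresholds(
    pooled: Sequence[float] | np.ndarray,
    scale: str = "",
    convention: str = "inverted_cdf",
) -> ThresholdSet:
    """Ranked-percentile table (n = 100) with low (60th) and high (95th) cutoffs.

    ``convention`` is any percentile method accepted by ``numpy.percentile``;
    the default ``inverted_cdf`` realizes ranked percentiles: the p-th entry
    is the smallest pooled value with empirical CDF >= p/100.  At least 20
    pooled values are required (>= 100 recommended).
    """
    values = np.asarray(pooled, dtype=float)
    if len(values) < 20:
        raise InsufficientDataError(f"need >= 20 pooled values, got {len(values)}")
    if np.ptp(values) == 0:
        logger.warning("percentile_thresholds: pooled values have no spread")
    if convention == "inverted_cdf":
        # exact integer rank arithmetic: the p-th ranked percentile is the
        # ceil(p*n/100)-th order statistic (numpy's float q introduces
        # off-by-one ranks at e.g. p=7)
        srt = np.sort(values)
        n = len(srt)
        ranks = [-(-p * n // 100) for p in range(1, 101)]
        pct = np.array([srt[r - 1] for r in ranks], dtype=float)
        low = float(pct[LOW_PERCENTILE - 1])
        high = float(pct[HIGH_PERCENTILE - 1])
    else:
        pct = np.percentile(values, np.arange(1, 101), method=convention)
        low = float(np.percentile(values, LOW_PERCENTILE, method=convention))
        high = float(np.percentile(values, HIGH_PERCENTILE, method=convention))
    return ThresholdSet(scale, pct, low, high, convention, len(values))


def classify_windows(series: InstabilitySeries, thresholds: ThresholdSet) -> InstabilitySeries:
    """Assign low/moderate/high categories to each window from the cutoffs.

    A raw variance at or below the 60th-percentile cutoff is low, at or above
    the 95th-percentile cutoff is high, otherwise moderate.  Mutates and
    returns the series.
    """
    if thresholds.scale and thresholds.scale != series.scale:
        raise ValidationError(
            f"threshold scale {thresholds.scale!r} != series scale {series.scale!r}"
        )
    for w in series.windows:
        if w.raw_variance <= thresholds.low_cutoff:
            w.category = Category.LOW
        elif w.raw_variance >= thresholds.high_cutoff:
            w.category = Category.HIGH
        else:
            w.category = Category.MODERATE
    return series


def participant_threshold(
    series: InstabilitySeries,
    thresholds: Optional[ThresholdSet] = None,
    rule: str = "max_attained",
) -> Optional[ParticipantThreshold]:
    """Collapse a participant's classified windows to one categorical threshold.

    ``max_attained`` (default): the highest category reached by any window —
    a participant who ever exceeds the high cutoff counts as high.
    ``median_window``: the classification of the participant's median raw
    variance (requires ``thresholds``); a robust sensitivity alternative.
    The continuous index is the participant mean of z-scaled window values
    under both rules.  Returns ``None`` (with a log note) for an empty series.
    """
    if not series.windows:
        logger.info(
            "participant_threshold: %s/%s has no windows; excluded",
            series.participant_id, series.scale,
        )
        return None
    if any(w.category is None for w in series.windows):
        raise ValueError("windows must be classified before participant_threshold")
    zs = [w.z_value for w in series.windows if w.z_value is not None]
    cont = float(np.mean(zs)) if zs else float("nan")
    if rule == "max_attained":
        cat = max(w.category for w in series.windows)
    elif rule == "median_window":
        if thresholds is None:
            raise ValueError("median_window rule requires thresholds")
        med = float(np.median(series.raw()))
        if med <= thresholds.low_cutoff:
            cat = Category.LOW
        elif med >= thresholds.high_cutoff:
            cat = Category.HIGH
        else:
            cat = Category.MODERATE
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return ParticipantThreshold(series.participant_id, series.scale, cont, cat)
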