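"""End-to-end pipeline: data -> rolling variance -> thresholds -> models -> report.

Stage order: read or simulate the cohort; per scale compute rolling variances
(optionally re-deriving the window width from LOESS diagnostics on a seeded
12:4:4 BD:PC:HC subsample); z-scale against the pooled distribution; derive
ranked-percentile thresholds; classify windows and participants; fit the
group-contrast mixed model, membership chi-squares, and the functioning
models.  Every stage writes plain CSV/JSON so stages can be rerun or mixed
with external tools, and a run manifest records config, seed and conventions
sufficient to reproduce every table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    ALPHA,
    FunctioningModelSpec,
    ModelSpecError,
    fit_functioning_model,
    instability_group_model,
    threshold_membership_test,
)
from .cohort import SyntheticCohortConfig, generate_cohort, study_shaped_preset
from .instability import (
    CANDIDATE_WIDTHS,
    Category,
    DEFAULT_LOESS_SPAN,
    DEFAULT_WIDTH,
    classify_windows,
    participant_threshold,
    percentile_thresholds,
    rolling_variance,
    select_window,
    window_diagnostics,
    zscale,
)
from .proms import Group, LongitudinalDataset, read_dataset, write_dataset

logger = logging.getLogger(__name__)

ALL_SCALES = ("PHQ9", "ASRM", "GAD7")


@dataclass
class PipelineConfig:
    """Run configuration; ``window='auto'`` re-derives the width from diagnostics."""

    input_path: Optional[str] = None
    preset: Optional[str] = None  # "study-shaped" or "small"
    scales: tuple[str, ...] = ALL_SCALES
    window: int | str = DEFAULT_WIDTH  # 3, 6, 12 or "auto"
    percentile_convention: str = "inverted_cdf"
    threshold_rule: str = "max_attained"
    loess_span: float = DEFAULT_LOESS_SPAN
    alpha: float = ALPHA
    out_dir: str = "mood_instability_out"
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.window != "auto" and self.window not in CANDIDATE_WIDTHS:
            raise ValueError(f"window must be one of {CANDIDATE_WIDTHS} or 'auto'")


def _load_or_simulate(config: PipelineConfig) -> LongitudinalDataset:
    if config.input_path:
        return read_dataset(config.input_path)
    if config.preset == "study-shaped":
        cc = study_shaped_preset(seed=config.seed)
    elif config.preset in (None, "small"):
        cc = SyntheticCohortConfig(seed=config.seed)
    else:
        raise ValueError(f"unknown preset {config.preset!r}")
    ds, _ = generate_cohort(cc)
    return ds


def window_selection_subsample(
    ds: LongitudinalDataset, seed: int, n_bd: int = 12, n_pc: int = 4, n_hc: int = 4
) -> list[str]:
    """Seeded participant subsample at the 12:4:4 BD:PC:HC ratio for diagnostics."""
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for group, n in ((Group.BD, n_bd), (Group.PC, n_pc), (Group.HC, n_hc)):
        pool = sorted(
            pid for pid, p in ds.participants.items() if p.group is group
        )
        take = min(n, len(pool))
        if take < n:
            logger.warning("subsample: only %d %s participants available", take, group.value)
        chosen.extend(rng.choice(pool, size=take, replace=False))
    return chosen


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all artifacts; returns a result dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        result = _run(config, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return result


def _run(config: PipelineConfig, out: Path) -> dict:
    ds = _load_or_simulate(config)
    write_dataset(ds, out / "dataset.csv")

    groups_present = {p.group.value for p in ds.participants.values()}
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "alpha": config.alpha,
        "percentile_convention": config.percentile_convention,
        "threshold_rule": config.threshold_rule,
        "scales": {},
    }
    result: dict = {"scales": {}, "out_dir": str(out)}

    window_rows, participant_rows, contrast_rows, chi_rows, model_rows = [], [], [], [], []

    for scale in config.scales:
        series_list = ds.series_for_scale(scale)
        k = config.window
        diagnostics = None
        if k == "auto":
            sub = set(window_selection_subsample(ds, config.seed))
            diag_input = [
                rolling_variance(s, kk)
                for kk in CANDIDATE_WIDTHS
                for s in series_list
                if s.participant_id in sub
            ]
            diagnostics = window_diagnostics(diag_input, config.loess_span)
            k = select_window(diagnostics)
            logger.info("%s: auto-selected window width k=%d", scale, k)

        inst = [rolling_variance(s, k) for s in series_list]
        inst = [s for s in inst if s.windows]
        if len(inst) < 2:
            logger.warning("%s: too few participants with windows; skipping scale", scale)
            continue
        zscale(inst)
        pooled = np.concatenate([s.raw() for s in inst])
        thresholds = percentile_thresholds(pooled, scale, config.percentile_convention)
        thresholds.to_json(out / f"thresholds_{scale}.json")
        for s in inst:
            classify_windows(s, thresholds)
        pt = [
            t
            for s in inst
            if (t := participant_threshold(s, thresholds, config.threshold_rule))
        ]

        for s in inst:
            for w in s.windows:
                window_rows.append(
                    (s.participant_id, scale, w.end_time_index, w.raw_variance,
                     w.z_value, w.category.label)
                )
        for t in pt:
            participant_rows.append(
                (t.participant_id, scale, t.continuous_index, t.category.label)
            )

        scale_result = {
            "window_width": k,
            "n_windows": int(sum(len(s.windows) for s in inst)),
            "n_participants": len(pt),
            "low_cutoff": thresholds.low_cutoff,
            "high_cutoff": thresholds.high_cutoff,
        }
        if diagnostics:
            scale_result["diagnostics"] = [dataclasses.asdict(d) for d in diagnostics]

        if len(groups_present) >= 2:
            try:
                contrasts = instability_group_model(
                    inst, ds.participants, scale, config.alpha
                )
                scale_result["contrasts"] = [dataclasses.asdict(c) for c in contrasts]
                for c in contrasts:
                    contrast_rows.append(
                        (scale, f"{c.contrast[0]}-{c.contrast[1]}", c.estimate,
                         c.standardized_effect, c.ci_low, c.ci_high, c.p_value,
                         c.significant)
                    )
                for cat in Category:
                    t = threshold_membership_test(pt, cat, ds.participants, config.alpha)
                    chi_rows.append(
                        (scale, cat.label, t.chi_square, t.df, t.p_value, t.significant)
                    )
            except ModelSpecError as exc:
                logger.warning("%s: group analyses skipped (%s)", scale, exc)
        else:
            logger.warning(
                "%s: only one diagnostic group present; group contrasts skipped", scale
            )

        if ds.functioning and len(groups_present) >= 2:
            for outcome in ("MCS", "PCS"):
                try:
                    fitres = fit_functioning_model(
                        ds, pt, FunctioningModelSpec(outcome, config.alpha)
                    )
                    for term, row in fitres.estimates.iterrows():
                        model_rows.append(
                            (scale, outcome, term, row.estimate, row.ci_low,
                             row.ci_high, row.p_value, row.significant)
                        )
                except (ModelSpecError, ValueError) as exc:
                    logger.warning("%s/%s functioning model skipped (%s)", scale, outcome, exc)

        result["scales"][scale] = scale_result
        manifest["scales"][scale] = {
            "window_width": k,
            "low_cutoff": thresholds.low_cutoff,
            "high_cutoff": thresholds.high_cutoff,
        }

        if config.make_plots:
            try:
                from .plots import plot_variance_distribution

                plot_variance_distribution(
                    inst, thresholds, ds.participants, out / f"variance_{scale}.png"
                )
            except Exception as exc:  # plotting is best-effort, never fails a run
                logger.warning("plotting failed for %s: %s", scale, exc)

    pd.DataFrame(
        window_rows,
        columns=["participant_id", "scale", "end_time_index", "raw_variance",
                 "z_value", "category"],
    ).to_csv(out / "instability_windows.csv", index=False)
    pd.DataFrame(
        participant_rows,
        columns=["participant_id", "scale", "continuous_index", "category"],
    ).to_csv(out / "participant_thresholds.csv", index=False)
    pd.DataFrame(
        contrast_rows,
        columns=["scale", "contrast", "estimate", "standardized_effect",
                 "ci_low", "ci_high", "p_tukey", "significant"],
    ).to_csv(out / "group_contrasts.csv", index=False)
    pd.DataFrame(
        chi_rows,
        columns=["scale", "category", "chi_square", "df", "p_value", "significant"],
    ).to_csv(out / "membership_tests.csv", index=False)
    pd.DataFrame(
        model_rows,
        columns=["scale", "outcome", "term", "estimate", "ci_low", "ci_high",
                 "p_value", "significant"],
    ).to_csv(out / "functioning_models.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
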