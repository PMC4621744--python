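"""Cohort-level orchestration: run the full unit quantification per session.

Ties together binning, baseline Z-normalization, response classification,
peri-stimulus curves/AUC, latency and concatenated percent-change into one
tidy table per cohort, keyed by unit, day and stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import spike_analysis as sa
from .protocol import EpochLabel, EventSchedule, SpikeTrain, trials_from_schedule

__all__ = ["AnalysisConfig", "analyze_unit_session", "analyze_cohort"]

STIMULI = (EpochLabel.US, EpochLabel.CS_PLUS, EpochLabel.CS_MINUS)


@dataclass(frozen=True)
class AnalysisConfig:
    classify_bin_s: float = sa.DEFAULT_CLASSIFY_BIN_S
    latency_bin_s: float = sa.DEFAULT_LATENCY_BIN_S
    curve_bin_s: float = sa.DEFAULT_CURVE_BIN_S
    upper_z: float = sa.UPPER_Z_THRESHOLD
    lower_z: float = sa.LOWER_Z_THRESHOLD
    response_window_s: float = sa.RESPONSE_WINDOW_S
    auc_window_s: tuple[float, float] = sa.DEFAULT_AUC_WINDOW_S
    curve_pre_s: float = 1.0
    curve_post_s: float = 2.0
    stimuli: tuple[EpochLabel, ...] = STIMULI


def _mean_z_trace(curve: sa.ResponseCurve, bin_s: float, unit_id: str) -> sa.ZScoreTrace:
    edges = np.append(curve.time_s - bin_s / 2, curve.time_s[-1] + bin_s / 2)
    return sa.ZScoreTrace(edges, curve.mean_z, unit_id=unit_id, alignment="stimulus-locked")


def analyze_unit_session(
    train: SpikeTrain,
    schedule: EventSchedule,
    config: AnalysisConfig | None = None,
) -> tuple[list[dict], dict[EpochLabel, sa.ResponseCurve]]:
    """Quantify one unit in one session.

    Returns one tidy record per stimulus (label, peak Z, latency, AUC,
    percent change) and the display-resolution response curves.  Units with a
    zero-variance baseline come back UNCLASSIFIABLE with NaN metrics.
    """
    config = config or AnalysisConfig()
    base = schedule.epochs_by_label(EpochLabel.BASELINE)[0]
    edges = np.arange(base.onset_s, base.end_s + config.classify_bin_s / 2, config.classify_bin_s)
    session_rates = sa.bin_rates(train, edges)
    stats = sa.baseline_stats(session_rates, (base.onset_s, base.end_s), schedule)

    rows: list[dict] = []
    curves: dict[EpochLabel, sa.ResponseCurve] = {}
    for stim in config.stimuli:
        trials = trials_from_schedule(schedule, stim)
        if not trials:
            continue
        row = {
            "unit_id": train.unit_id,
            "genotype": train.genotype.value,
            "day": schedule.day,
            "stimulus": stim.value,
            "baseline_rate_hz": stats.mean_rate_hz,
        }
        if stats.degenerate:
            row.update(
                label=sa.ResponseLabel.UNCLASSIFIABLE.value,
                peak_z=np.nan, latency_s=np.nan, auc=np.nan, percent_change=np.nan,
            )
            rows.append(row)
            continue

        cls_curve = sa.peristimulus_curve(
            train, trials, stats,
            pre_s=config.response_window_s, post_s=config.response_window_s * 2,
            bin_s=config.classify_bin_s, auc_window_s=config.auc_window_s,
        )
        cls = sa.classify_unit(
            _mean_z_trace(cls_curve, config.classify_bin_s, train.unit_id),
            stimulus=stim, upper=config.upper_z, lower=config.lower_z,
            window_s=config.response_window_s,
        )

        latency_s = np.nan
        if cls.label in (sa.ResponseLabel.ACTIVATED, sa.ResponseLabel.INHIBITED):
            fine = sa.peristimulus_curve(
                train, trials, stats,
                pre_s=0.0, post_s=config.response_window_s,
                bin_s=config.latency_bin_s, auc_window_s=config.auc_window_s,
            )
            thr = config.upper_z if cls.label is sa.ResponseLabel.ACTIVATED else config.lower_z
            lat = sa.response_latency(
                _mean_z_trace(fine, config.latency_bin_s, train.unit_id),
                threshold=thr, max_window_s=config.response_window_s,
            )
            if not lat.censored:
                latency_s = lat.latency_s

        curve = sa.peristimulus_curve(
            train, trials, stats,
            pre_s=config.curve_pre_s, post_s=config.curve_post_s,
            bin_s=config.curve_bin_s, auc_window_s=config.auc_window_s,
        )
        curves[stim] = curve

        if stim in (EpochLabel.CS_PLUS, EpochLabel.CS_MINUS):
            spans = trials_from_schedule(schedule, stim, include_iti=True)
            pct = sa.concatenated_change(train, spans, stats)
        else:
            pct = np.nan

        row.update(
            label=cls.label.value,
            peak_z=cls.peak_z,
            latency_s=latency_s,
            auc=curve.auc,
            percent_change=pct,
        )
        rows.append(row)
    return rows, curves


def analyze_cohort(
    trains: list[SpikeTrain],
    schedules: list[EventSchedule],
    config: AnalysisConfig | None = None,
    return_curves: bool = False,
):
    """Run the per-unit quantification over a cohort of sessions.

    Schedules are matched to trains by day.  Returns a tidy DataFrame (one
    row per unit x day x stimulus) and, if requested, the response curves
    keyed by (unit_id, day, stimulus).
    """
    by_day = {s.day: s for s in schedules}
    all_rows: list[dict] = []
    all_curves: dict[tuple, sa.ResponseCurve] = {}
    for train in trains:
        sched = by_day.get(train.day)
        if sched is None:
            raise KeyError(f"no schedule for day {train.day} (unit {train.unit_id})")
        rows, curves = analyze_unit_session(train, sched, config)
        all_rows.extend(rows)
        for stim, c in curves.items():
            all_curves[(train.unit_id, train.day, stim.value)] = c
    columns = [
        "unit_id", "genotype", "day", "stimulus", "baseline_rate_hz",
        "label", "peak_z", "latency_s", "auc", "percent_change",
    ]
    df = pd.DataFrame(all_rows, columns=columns)
    if return_curves:
        return df, all_curves
    return df
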