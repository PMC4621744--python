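"""In vivo unit quantification: Z-scoring, response classification, PSTH/AUC.

Firing is binned and normalized to the pre-trial baseline with a Z-score,
Z = (R_i - R_m) / S.D., where R_i is the rate in bin i and R_m and S.D. are
the mean and sample standard deviation of the baseline bin rates.  A unit is
ACTIVATED by a stimulus if Z exceeds 1 within the first 500 ms after stimulus
onset and INHIBITED if (not activated and) Z falls below -0.5 in that window.
Plasticity across conditioning days is read out as the area under the
trial-averaged Z curve (AUC) on a post-onset window, and overall excitability
as the percent change of the rate over concatenated trial+ITI spans relative
to baseline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .protocol import (
    EpochLabel,
    EventSchedule,
    SpikeTrain,
    TrialWindow,
    ValidationError,
)
from .stats import Ecdf, ecdf, sem

__all__ = [
    "ResponseLabel",
    "BinnedRates",
    "BaselineStats",
    "ZScoreTrace",
    "UnitClassification",
    "ResponseCurve",
    "UnclassifiableBaseline",
    "bin_rates",
    "baseline_stats",
    "zscore",
    "classify_unit",
    "peristimulus_curve",
    "concatenated_change",
    "response_latency",
    "latency_cdf",
    "auc_of_curve",
    "discrimination_contrast",
    "population_summary",
    "DEFAULT_CLASSIFY_BIN_S",
    "DEFAULT_LATENCY_BIN_S",
    "DEFAULT_CURVE_BIN_S",
]

# Bin widths: 100 ms for classification (five bins tile the 500 ms decision
# window), 20 ms for latency resolution, 50 ms for display curves.
DEFAULT_CLASSIFY_BIN_S = 0.1
DEFAULT_LATENCY_BIN_S = 0.02
DEFAULT_CURVE_BIN_S = 0.05

UPPER_Z_THRESHOLD = 1.0
LOWER_Z_THRESHOLD = -0.5
RESPONSE_WINDOW_S = 0.5
DEFAULT_AUC_WINDOW_S = (0.0, 1.0)


class ResponseLabel(str, enum.Enum):
    ACTIVATED = "ACTIVATED"
    INHIBITED = "INHIBITED"
    NON_RESPONSIVE = "NON_RESPONSIVE"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"


class UnclassifiableBaseline(ValueError):
    """Baseline variance is zero, so Z-scores are undefined."""


@dataclass(frozen=True)
class BinnedRates:
    """Per-bin firing rate: spike count in [e_k, e_{k+1}) / bin width."""

    bin_edges_s: np.ndarray
    rates_hz: np.ndarray
    alignment: str = "session"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges_s", np.asarray(self.bin_edges_s, float))
        object.__setattr__(self, "rates_hz", np.asarray(self.rates_hz, float))
        if self.rates_hz.size != self.bin_edges_s.size - 1:
            raise ValidationError("need len(rates) == len(edges) - 1")


@dataclass(frozen=True)
class BaselineStats:
    """Baseline mean rate (R_m) and sample standard deviation (S.D.)."""

    mean_rate_hz: float
    sd_rate_hz: float
    n_bins: int
    window_s: tuple[float, float]

    @property
    def degenerate(self) -> bool:
        return self.sd_rate_hz == 0.0


@dataclass(frozen=True)
class ZScoreTrace:
    """Baseline-normalized binned firing, stimulus- or session-aligned."""

    bin_edges_s: np.ndarray
    z: np.ndarray
    unit_id: str = "unit"
    alignment: str = "session"

    @property
    def bin_width_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])


@dataclass(frozen=True)
class UnitClassification:
    unit_id: str
    stimulus: EpochLabel
    label: ResponseLabel
    window_s: float = RESPONSE_WINDOW_S
    peak_z: float = float("nan")
    latency_s: float | None = None


@dataclass(frozen=True)
class ResponseCurve:
    """Trial-averaged stimulus-locked Z with sem and response-window AUC."""

    time_s: np.ndarray
    mean_z: np.ndarray
    sem_z: np.ndarray
    n_trials: int
    auc: float
    auc_window_s: tuple[float, float]
    trial_z: np.ndarray  # (n_trials, n_bins), per-trial Z traces
    unit_id: str = "unit"
    stimulus: EpochLabel | None = None


def bin_rates(
    train: SpikeTrain, edges_s: np.ndarray, alignment: str = "session"
) -> BinnedRates:
    edges = np.asarray(edges_s, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing")
    counts, _ = np.histogram(train.timestamps_s, bins=edges)
    # np.histogram closes the final bin on the right; re-open it to keep every
    # bin half-open [e_k, e_{k+1})
    if train.timestamps_s.size and train.timestamps_s[-1] == edges[-1]:
        counts[-1] -= 1
    return BinnedRates(edges, counts / np.diff(edges), alignment=alignment)


def baseline_stats(
    rates: BinnedRates,
    baseline_window_s: tuple[float, float],
    schedule: EventSchedule | None = None,
) -> BaselineStats:
    """Mean and sample sd (ddof=1) of the rates over baseline bins only.

    If a schedule is given, the window must lie within its BASELINE epoch.
    """
    start, end = baseline_window_s
    if schedule is not None:
        base = schedule.epochs_by_label(EpochLabel.BASELINE)
        inside = any(b.onset_s <= start and end <= b.end_s + 1e-9 for b in base)
        if not inside:
            raise ValidationError(
                f"window {baseline_window_s} is not inside the BASELINE epoch"
            )
    edges = rates.bin_edges_s
    mask = (edges[:-1] >= start - 1e-9) & (edges[1:] <= end + 1e-9)
    vals = rates.rates_hz[mask]
    if vals.size < 2:
        raise ValidationError("need at least 2 baseline bins")
    return BaselineStats(
        mean_rate_hz=float(np.mean(vals)),
        sd_rate_hz=float(np.std(vals, ddof=1)),
        n_bins=int(vals.size),
        window_s=(start, end),
    )


def zscore(
    rates: BinnedRates, stats: BaselineStats, unit_id: str = "unit"
) -> ZScoreTrace:
    """Z_k = (rate_k - R_m) / S.D., elementwise."""
    if stats.degenerate:
        raise UnclassifiableBaseline(
            "baseline sd is 0; Z-scores are undefined for this unit"
        )
    z = (rates.rates_hz - stats.mean_rate_hz) / stats.sd_rate_hz
    return ZScoreTrace(rates.bin_edges_s, z, unit_id=unit_id, alignment=rates.alignment)


def _first_crossing(z: ZScoreTrace, threshold: float, window_s: float, above: bool):
    """(crossed, latency of the left edge of the first crossing bin)."""
    starts = z.bin_edges_s[:-1]
    m = (starts >= -1e-12) & (starts < window_s - 1e-12)
    vals = z.z[m]
    hits = vals > threshold if above else vals < threshold
    if not np.any(hits):
        return False, None
    return True, float(starts[m][np.argmax(hits)])


def classify_unit(
    z: ZScoreTrace,
    stimulus: EpochLabel = EpochLabel.US,
    upper: float = UPPER_Z_THRESHOLD,
    lower: float = LOWER_Z_THRESHOLD,
    window_s: float = RESPONSE_WINDOW_S,
) -> UnitClassification:
    """Label a stimulus-aligned Z trace as ACTIVATED/INHIBITED/NON_RESPONSIVE.

    ACTIVATED if any bin within [0, window) exceeds ``upper``; otherwise
    INHIBITED if any bin falls below ``lower``; otherwise NON_RESPONSIVE.
    Records the peak |Z| bin value and the first-crossing latency.
    """
    starts = z.bin_edges_s[:-1]
    if starts.size == 0 or starts[0] > 1e-12 or z.bin_edges_s[-1] < window_s - 1e-9:
        raise ValidationError("Z trace must cover the full [0, window) span")
    m = (starts >= -1e-12) & (starts < window_s - 1e-12)
    vals = z.z[m]
    act, act_lat = _first_crossing(z, upper, window_s, above=True)
    if act:
        return UnitClassification(
            z.unit_id, stimulus, ResponseLabel.ACTIVATED, window_s,
            peak_z=float(np.max(vals)), latency_s=act_lat,
        )
    inh, inh_lat = _first_crossing(z, lower, window_s, above=False)
    if inh:
        return UnitClassification(
            z.unit_id, stimulus, ResponseLabel.INHIBITED, window_s,
            peak_z=float(np.min(vals)), latency_s=inh_lat,
        )
    peak = float(vals[np.argmax(np.abs(vals))]) if vals.size else float("nan")
    return UnitClassification(
        z.unit_id, stimulus, ResponseLabel.NON_RESPONSIVE, window_s,
        peak_z=peak, latency_s=None,
    )


def auc_of_curve(
    time_s: np.ndarray, values: np.ndarray, window_s: tuple[float, float]
) -> float:
    """Trapezoidal area under a sampled curve restricted to a time window."""
    time_s = np.asarray(time_s, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = window_s
    m = (time_s >= lo) & (time_s <= hi)
    if m.sum() < 2:
        return float("nan")
    return float(trapezoid(values[m], time_s[m]))


def peristimulus_curve(
    train: SpikeTrain,
    trials: list[TrialWindow],
    stats: BaselineStats,
    pre_s: float = 1.0,
    post_s: float = 2.0,
    bin_s: float = DEFAULT_CURVE_BIN_S,
    auc_window_s: tuple[float, float] = DEFAULT_AUC_WINDOW_S,
) -> ResponseCurve:
    """Trial-averaged stimulus-aligned Z curve with sem and trapezoidal AUC.

    Each trial is binned on [-pre, post) around its onset, Z-scored against
    the session baseline stats, and averaged across trials; the AUC is the
    trapezoidal integral of the mean curve over ``auc_window_s`` (bin
    centers), in units of Z x seconds.
    """
    if not trials:
        raise ValidationError("need at least 1 trial")
    stimuli = {t.stimulus for t in trials}
    if len(stimuli) > 1:
        raise ValidationError(f"trials mix stimuli: {sorted(s.value for s in stimuli)}")
    if stats.degenerate:
        raise UnclassifiableBaseline("baseline sd is 0")
    n_bins = int(round((pre_s + post_s) / bin_s))
    rel_edges = -pre_s + bin_s * np.arange(n_bins + 1)
    trial_z = np.empty((len(trials), n_bins))
    for i, tw in enumerate(trials):
        binned = bin_rates(train, tw.onset_s + rel_edges, alignment="stimulus-locked")
        trial_z[i] = (binned.rates_hz - stats.mean_rate_hz) / stats.sd_rate_hz
    mean_z = trial_z.mean(axis=0)
    sem_z = (
        sem(trial_z, axis=0) if len(trials) > 1 else np.full(n_bins, np.nan)
    )
    centers = rel_edges[:-1] + bin_s / 2
    auc = auc_of_curve(centers, mean_z, auc_window_s)
    return ResponseCurve(
        time_s=centers,
        mean_z=mean_z,
        sem_z=sem_z,
        n_trials=len(trials),
        auc=auc,
        auc_window_s=auc_window_s,
        trial_z=trial_z,
        unit_id=train.unit_id,
        stimulus=trials[0].stimulus,
    )


def concatenated_change(
    train: SpikeTrain, trials: list[TrialWindow], stats: BaselineStats
) -> float:
    """Percent change of the concatenated trial(+ITI) rate vs baseline.

    100 x (mean rate over the concatenated spans - R_m) / R_m.  Trials should
    include their subsequent ITIs (``include_iti=True`` windows).
    """
    if not trials:
        raise ValidationError("need at least 1 trial span")
    if stats.mean_rate_hz == 0:
        raise UnclassifiableBaseline("baseline mean rate is 0; percent change undefined")
    total_time = sum(t.duration_s for t in trials)
    total_spikes = sum(train.count_in(t.onset_s, t.end_s) for t in trials)
    rate = total_spikes / total_time
    return 100.0 * (rate - stats.mean_rate_hz) / stats.mean_rate_hz


@dataclass(frozen=True)
class LatencyResult:
    latency_s: float | None
    censored: bool


def response_latency(
    z: ZScoreTrace, threshold: float = UPPER_Z_THRESHOLD, max_window_s: float = RESPONSE_WINDOW_S
) -> LatencyResult:
    """Left edge of the first bin crossing ``threshold``; censored if none.

    Use a fine-binned Z trace (20 ms default elsewhere) for usable resolution.
    A negative threshold is interpreted as a downward crossing.
    """
    above = threshold >= 0
    crossed, lat = _first_crossing(z, threshold, max_window_s, above=above)
    return LatencyResult(latency_s=lat, censored=not crossed)


def latency_cdf(latencies: list[LatencyResult | float]) -> Ecdf:
    """Right-continuous ECDF over uncensored latencies; censored count kept."""
    vals, censored = [], 0
    for item in latencies:
        if isinstance(item, LatencyResult):
            if item.censored:
                censored += 1
            else:
                vals.append(item.latency_s)
        else:
            vals.append(float(item))
    if not vals:
        raise ValidationError("all latencies censored; ECDF undefined")
    return ecdf(vals, n_censored=censored)


def discrimination_contrast(
    csp_curves: list[ResponseCurve],
    csm_curves: list[ResponseCurve],
    response_window_s: tuple[float, float] = DEFAULT_AUC_WINDOW_S,
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> dict:
    """CS+ vs CS- discrimination for matched units.

    Per unit: mean Z over the response window, CS+ minus CS-.  The group
    p-value comes from shuffling trial labels within each unit (pooling that
    unit's CS+ and CS- trials) and recomputing the group mean contrast.
    """
    csp_by_unit = {c.unit_id: c for c in csp_curves}
    csm_by_unit = {c.unit_id: c for c in csm_curves}
    units = sorted(set(csp_by_unit) & set(csm_by_unit))
    if not units:
        raise ValidationError("no units with both CS+ and CS- curves")

    def trial_means(curve: ResponseCurve) -> np.ndarray:
        lo, hi = response_window_s
        m = (curve.time_s >= lo) & (curve.time_s <= hi)
        return curve.trial_z[:, m].mean(axis=1)

    per_unit = {}
    pools, n_ps = [], []
    for u in units:
        a = trial_means(csp_by_unit[u])
        b = trial_means(csm_by_unit[u])
        per_unit[u] = float(a.mean() - b.mean())
        pools.append(np.concatenate([a, b]))
        n_ps.append(a.size)
    observed = float(np.mean(list(per_unit.values())))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        stat = 0.0
        for pool, n_p in zip(pools, n_ps):
            perm = rng.permutation(pool)
            stat += perm[:n_p].mean() - perm[n_p:].mean()
        stat /= len(pools)
        if abs(stat) >= abs(observed) - 1e-15:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return {
        "per_unit": per_unit,
        "mean_contrast": observed,
        "sem_contrast": float(sem(list(per_unit.values()))),
        "p_value": p,
        "n_units": len(units),
    }


def population_summary(
    classifications: pd.DataFrame, changes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Label counts/proportions per (genotype, day, stimulus) cell.

    ``classifications`` needs columns unit_id, genotype, day, stimulus, label;
    ``changes`` (optional) needs unit_id, genotype, day, stimulus,
    percent_change and contributes per-cell mean +/- sem percent change.
    """
    if classifications.empty:
        raise ValidationError("no classifications to summarize")
    keys = ["genotype", "day", "stimulus"]
    rows = []
    for cell, grp in classifications.groupby(keys):
        n = len(grp)
        counts = grp["label"].value_counts()
        row = dict(zip(keys, cell))
        row["n_units"] = n
        for label in ResponseLabel:
            c = int(counts.get(label.value, counts.get(label, 0)))
            row[f"n_{label.value.lower()}"] = c
            row[f"prop_{label.value.lower()}"] = c / n
        rows.append(row)
    out = pd.DataFrame(rows)
    if changes is not None and not changes.empty:
        agg = (
            changes.groupby(keys)["percent_change"]
            .agg(mean_percent_change="mean", sem_percent_change=sem)
            .reset_index()
        )
        out = out.merge(agg, on=keys, how="left")
    return out
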