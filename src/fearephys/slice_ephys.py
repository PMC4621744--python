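"""Ex vivo quantification: PSP decomposition, E/I ratio, miniature-event stats.

Evoked compound postsynaptic potentials (PSPs) mix excitatory and inhibitory
components.  The EPSP is isolated pharmacologically (GABA-A blockade); the
IPSP is then recovered by digital subtraction of the averaged EPSP from the
averaged compound PSP, and the EPSP:IPSP amplitude ratio gives a normalized
excitation/inhibition index.  Miniature postsynaptic currents (minis) are
detected as threshold crossings on a detrended voltage-clamp trace; their
frequency indexes presynaptic release, their amplitude postsynaptic strength.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .stats import ecdf, permutation_pvalue

__all__ = [
    "Modality",
    "Condition",
    "SweepTrace",
    "PSPDecomposition",
    "MiniEventSet",
    "GridMismatchError",
    "average_sweeps",
    "isolate_ipsp",
    "psp_amplitude",
    "ei_ratio",
    "detect_minis",
    "mini_stats",
    "condition_contrast",
]


class Modality(str, enum.Enum):
    COMPOUND_PSP = "COMPOUND_PSP"
    EPSP_ISOLATED = "EPSP_ISOLATED"
    MINI_EPSC = "MINI_EPSC"
    MINI_IPSC = "MINI_IPSC"


class Condition(str, enum.Enum):
    NAIVE = "NAIVE"
    SHOCK = "SHOCK"


class GridMismatchError(ValueError):
    """Traces do not share a common sampling grid or alignment."""


@dataclass(frozen=True)
class SweepTrace:
    """One uniformly sampled intracellular sweep.

    Units are mV in current clamp (PSPs) and pA in voltage clamp (minis).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    modality: Modality
    stimulus_onset_s: float | None = None
    cell_id: str = "cell"
    condition: Condition = Condition.NAIVE
    genotype: str = "CONTROL"

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if arr.size < 2:
            raise ValueError("a sweep needs at least 2 samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_hz

    def _grid_key(self) -> tuple:
        return (self.samples.size, self.sampling_rate_hz, self.stimulus_onset_s)


@dataclass(frozen=True)
class PSPDecomposition:
    """Compound/EPSP/IPSP traces on a common grid plus amplitude summary.

    The IPSP is defined as the elementwise difference compound - EPSP (no
    filtering), so ``epsp + ipsp == compound`` holds exactly.
    """

    compound_avg: SweepTrace
    epsp_avg: SweepTrace
    ipsp: SweepTrace
    epsp_amplitude_mv: float
    ipsp_amplitude_mv: float
    ei_ratio: float


@dataclass(frozen=True)
class MiniEventSet:
    """Detected miniature events of one trace with derived statistics."""

    times_s: np.ndarray
    amplitudes: np.ndarray
    duration_s: float
    cell_id: str = "cell"
    condition: Condition = Condition.NAIVE
    genotype: str = "CONTROL"
    modality: Modality = Modality.MINI_EPSC

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "amplitudes", a)
        if t.size != a.size:
            raise ValueError("times and amplitudes must align")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("event times must be sorted")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    @property
    def n_events(self) -> int:
        return int(self.times_s.size)

    @property
    def frequency_hz(self) -> float:
        return self.n_events / self.duration_s

    @property
    def inter_event_intervals_s(self) -> np.ndarray:
        return np.diff(self.times_s)


def average_sweeps(traces: list[SweepTrace]) -> SweepTrace:
    """Pointwise mean of repeated sweeps from one cell (15-30 in practice)."""
    if not traces:
        raise ValueError("no sweeps to average")
    first = traces[0]
    for t in traces[1:]:
        if t._grid_key() != first._grid_key():
            raise GridMismatchError("sweeps are on different grids")
        if t.modality is not first.modality or t.cell_id != first.cell_id:
            raise ValueError("sweeps must share modality and cell")
    mean = np.mean([t.samples for t in traces], axis=0)
    return SweepTrace(
        samples=mean,
        sampling_rate_hz=first.sampling_rate_hz,
        modality=first.modality,
        stimulus_onset_s=first.stimulus_onset_s,
        cell_id=first.cell_id,
        condition=first.condition,
        genotype=first.genotype,
    )


def psp_amplitude(
    trace: SweepTrace,
    baseline_window_s: tuple[float, float],
    search_window_s: tuple[float, float],
    polarity: str,
) -> float:
    """Baseline-to-peak amplitude: |extremum in search window - baseline mean|."""
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    fs = trace.sampling_rate_hz
    n = trace.samples.size

    def _slice(window):
        i0 = max(0, int(np.ceil(window[0] * fs)))
        i1 = min(n, int(np.floor(window[1] * fs)) + 1)
        if i1 <= i0:
            raise ValueError(f"window {window} selects no samples")
        return trace.samples[i0:i1]

    base = float(np.mean(_slice(baseline_window_s)))
    seg = _slice(search_window_s)
    ext = float(np.max(seg)) if polarity == "positive" else float(np.min(seg))
    return abs(ext - base)


def ei_ratio(epsp_amplitude_mv: float, ipsp_amplitude_mv: float) -> float:
    if ipsp_amplitude_mv <= 0:
        raise ZeroDivisionError("IPSP amplitude must be > 0 for an E/I ratio")
    return epsp_amplitude_mv / ipsp_amplitude_mv


def isolate_ipsp(
    compound_avg: SweepTrace,
    epsp_avg: SweepTrace,
    *,
    baseline_window_s: tuple[float, float] | None = None,
    search_window_s: tuple[float, float] | None = None,
) -> PSPDecomposition:
    """Digitally subtract the averaged EPSP from the averaged compound PSP.

    Amplitudes are baseline-to-peak on a 50 ms pre-stimulus baseline and a
    200 ms post-stimulus search window by default (requires a stimulus onset
    on the traces); the EPSP is depolarizing (positive) and the IPSP trace,
    as compound - EPSP, is hyperpolarizing (negative).
    """
    if compound_avg._grid_key() != epsp_avg._grid_key():
        raise GridMismatchError("compound and EPSP averages are on different grids")
    diff = compound_avg.samples - epsp_avg.samples
    ipsp = SweepTrace(
        samples=diff,
        sampling_rate_hz=compound_avg.sampling_rate_hz,
        modality=Modality.COMPOUND_PSP,
        stimulus_onset_s=compound_avg.stimulus_onset_s,
        cell_id=compound_avg.cell_id,
        condition=compound_avg.condition,
        genotype=compound_avg.genotype,
    )
    onset = compound_avg.stimulus_onset_s
    if baseline_window_s is None:
        if onset is None:
            raise ValueError("traces need a stimulus onset for default windows")
        baseline_window_s = (max(0.0, onset - 0.05), onset)
    if search_window_s is None:
        if onset is None:
            raise ValueError("traces need a stimulus onset for default windows")
        search_window_s = (onset, onset + 0.2)
    e_amp = psp_amplitude(epsp_avg, baseline_window_s, search_window_s, "positive")
    i_amp = psp_amplitude(ipsp, baseline_window_s, search_window_s, "negative")
    ratio = ei_ratio(e_amp, i_amp) if i_amp > 0 else float("nan")
    return PSPDecomposition(
        compound_avg=compound_avg,
        epsp_avg=epsp_avg,
        ipsp=ipsp,
        epsp_amplitude_mv=e_amp,
        ipsp_amplitude_mv=i_amp,
        ei_ratio=ratio,
    )


# Detector polarity by modality: at -60 mV holding both mEPSCs and (with a
# high-chloride internal) mIPSCs are inward, i.e. negative-going.
_POLARITY = {Modality.MINI_EPSC: -1.0, Modality.MINI_IPSC: -1.0}


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise scale from the median absolute deviation (Gaussian-consistent)."""
    return float(np.median(np.abs(x - np.median(x))) / 0.6744897501960817)


def detect_minis(
    trace: SweepTrace,
    noise_sd_estimate: float | None = None,
    amp_threshold_multiplier: float = 3.0,
    min_interval_s: float = 0.005,
    max_rise_s: float = 0.005,
    detrend_window_s: float = 0.05,
    smooth_window_s: float = 0.001,
) -> MiniEventSet:
    """Detect miniature postsynaptic currents by threshold crossing.

    The trace is detrended with a moving-median baseline (window
    ``detrend_window_s``) and flipped to the polarity of the modality.  The
    noise sd is estimated robustly (median absolute deviation) on the raw
    detrended trace; peaks are then searched on a lightly smoothed copy
    (moving average over ``smooth_window_s``) so single-sample noise
    excursions cannot trigger, while the amplitude criterion
    ``amp_threshold_multiplier x raw noise sd`` keeps its conventional
    meaning.  Candidates closer than ``min_interval_s`` merge into the larger
    one, and candidates whose 10%-to-peak rise on the smoothed trace exceeds
    ``max_rise_s`` are rejected as non-synaptic.  Amplitudes are positive
    magnitudes of the raw detrended deflection at the peak.
    """
    if trace.modality not in _POLARITY:
        raise ValueError(f"{trace.modality.value} is not a mini recording")
    fs = trace.sampling_rate_hz
    win = max(3, int(round(detrend_window_s * fs)) | 1)
    baseline = ndimage.median_filter(trace.samples, size=win, mode="nearest")
    flipped = _POLARITY[trace.modality] * (trace.samples - baseline)
    sd = noise_sd_estimate if noise_sd_estimate is not None else robust_noise_sd(flipped)
    if sd <= 0:
        return MiniEventSet(
            times_s=np.empty(0),
            amplitudes=np.empty(0),
            duration_s=trace.duration_s,
            cell_id=trace.cell_id,
            condition=trace.condition,
            genotype=trace.genotype,
            modality=trace.modality,
        )
    smooth_n = max(1, int(round(smooth_window_s * fs)))
    smoothed = ndimage.uniform_filter1d(flipped, size=smooth_n, mode="nearest")
    height = amp_threshold_multiplier * sd
    distance = max(1, int(round(min_interval_s * fs)))
    peaks, _ = signal.find_peaks(smoothed, height=height, distance=distance)

    keep_idx = []
    max_rise_n = max(1, int(round(max_rise_s * fs)))
    for p in peaks:
        amp = smoothed[p]
        start = max(0, p - 4 * max_rise_n)
        below = np.nonzero(smoothed[start:p] < 0.1 * amp)[0]
        rise_n = p - (start + below[-1]) if below.size else p - start
        if rise_n <= max_rise_n:
            keep_idx.append(p)
    keep = np.asarray(keep_idx, dtype=int)
    if keep.size:
        # report amplitude from the unsmoothed deflection around each peak
        amps = np.array(
            [flipped[max(0, p - smooth_n): p + smooth_n + 1].max() for p in keep]
        )
    else:
        amps = np.empty(0)
    return MiniEventSet(
        times_s=keep / fs,
        amplitudes=amps,
        duration_s=trace.duration_s,
        cell_id=trace.cell_id,
        condition=trace.condition,
        genotype=trace.genotype,
        modality=trace.modality,
    )


def mini_stats(events: MiniEventSet) -> dict:
    """Frequency, mean amplitude, and ECDFs of amplitude and inter-event interval."""
    empty = events.n_events == 0
    return {
        "n_events": events.n_events,
        "frequency_hz": events.frequency_hz,
        "amplitude_mean": float(np.mean(events.amplitudes)) if not empty else float("nan"),
        "amplitude_ecdf": ecdf(events.amplitudes) if not empty else None,
        "iei_ecdf": (
            ecdf(events.inter_event_intervals_s) if events.n_events > 1 else None
        ),
        "empty": empty,
    }


def condition_contrast(
    values_by_condition: dict[Condition, np.ndarray],
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> dict:
    """Group comparison of a per-cell statistic between NAIVE and SHOCK.

    Returns the difference in group means (SHOCK - NAIVE) with a seeded
    permutation p-value over cell-label shuffles (two-sided).
    """
    naive = np.asarray(values_by_condition[Condition.NAIVE], dtype=float)
    shock = np.asarray(values_by_condition[Condition.SHOCK], dtype=float)
    if naive.size < 2 or shock.size < 2:
        raise ValueError("need at least 2 cells per condition")
    effect = float(np.mean(shock) - np.mean(naive))
    p = permutation_pvalue(shock, naive, n_permutations=n_permutations, seed=seed)
    return {
        "effect": effect,
        "p_value": p,
        "n_naive": int(naive.size),
        "n_shock": int(shock.size),
    }
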