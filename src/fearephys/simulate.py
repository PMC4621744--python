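"""Synthetic spike trains and intracellular traces with known ground truth.

Spike trains come from an inhomogeneous Poisson process: a constant baseline
rate modulated by stimulus-locked difference-of-exponentials kernels, sampled
by thinning.  Excitatory responses add to the baseline; inhibitory responses
suppress it multiplicatively (floored at zero).  Per-stimulus gains are
multiplied by a day-dependent trajectory, which is where the two presets
differ: ``control_like`` carries the plasticity expected of intact animals
(US response peaking on day 2, CS+ response growing across days, CS-
inhibition shrinking), while ``ko_like`` is flat across days, emulating the
knockout phenotype in which those trajectories are absent.

Intracellular sweeps are sums of kinetic waveforms plus Gaussian noise, with
optional miniature events placed by a homogeneous Poisson process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocol import EpochLabel, EventSchedule, Genotype, SpikeTrain
from .slice_ephys import Condition, Modality, SweepTrace

__all__ = [
    "DoeKernel",
    "StimulusResponse",
    "UnitResponseProfile",
    "CohortSpec",
    "TraceSpec",
    "Waveform",
    "MiniAmplitudeModel",
    "GeneratorError",
    "simulate_unit",
    "simulate_cohort",
    "simulate_sweep",
    "rate_function",
    "control_like_trajectories",
    "ko_like_trajectories",
    "default_class_profiles",
    "PROFILE_CLASSES",
]


class GeneratorError(ValueError):
    """A simulation spec would produce an invalid (e.g. negative-rate) process."""


@dataclass(frozen=True)
class DoeKernel:
    """Difference-of-exponentials kernel, peak-normalized to 1.

    k(t) = (exp(-t/decay) - exp(-t/rise)) / k_peak for t >= 0, zero before.
    Peak normalization makes a response gain directly interpretable as the
    peak fractional rate change.
    """

    rise_s: float
    decay_s: float

    def __post_init__(self) -> None:
        if not 0 < self.rise_s < self.decay_s:
            raise GeneratorError("need 0 < rise < decay for a well-formed kernel")

    @property
    def t_peak_s(self) -> float:
        r, d = self.rise_s, self.decay_s
        return r * d / (d - r) * math.log(d / r)

    @property
    def _norm(self) -> float:
        tp = self.t_peak_s
        return math.exp(-tp / self.decay_s) - math.exp(-tp / self.rise_s)

    @property
    def integral_s(self) -> float:
        """Closed-form integral of the normalized kernel over [0, inf)."""
        return (self.decay_s - self.rise_s) / self._norm

    def support_s(self, eps: float = 1e-4) -> float:
        """Time beyond which the kernel is below ``eps`` (conservative bound)."""
        return self.decay_s * math.log(1.0 / (eps * self._norm))

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        m = t >= 0
        tm = t[m]
        out[m] = (np.exp(-tm / self.decay_s) - np.exp(-tm / self.rise_s)) / self._norm
        return out


@dataclass(frozen=True)
class StimulusResponse:
    """Kinetics and gain of one unit's response to one stimulus type."""

    gain: float
    sign: str  # "excite" | "inhibit"
    latency_s: float = 0.02
    rise_s: float = 0.01
    decay_s: float = 0.15

    def __post_init__(self) -> None:
        if self.sign not in ("excite", "inhibit"):
            raise GeneratorError(f"sign must be excite|inhibit, got {self.sign!r}")
        if self.gain < 0 or self.latency_s < 0:
            raise GeneratorError("gain and latency must be >= 0")

    @property
    def kernel(self) -> DoeKernel:
        return DoeKernel(self.rise_s, self.decay_s)


@dataclass(frozen=True)
class UnitResponseProfile:
    """Ground-truth firing model of one simulated unit.

    ``day_trajectory`` maps stimulus -> {day -> gain multiplier}; missing
    entries default to 1.  For an inhibitory response, gain x multiplier must
    stay <= 1 so the suppressed rate cannot go negative.
    """

    baseline_rate_hz: float
    responses: dict[EpochLabel, StimulusResponse] = field(default_factory=dict)
    day_trajectory: dict[EpochLabel, dict[int, float]] = field(default_factory=dict)
    profile_class: str = "custom"

    def __post_init__(self) -> None:
        if self.baseline_rate_hz <= 0:
            raise GeneratorError("baseline rate must be > 0")
        for stim, resp in self.responses.items():
            if resp.sign == "inhibit":
                mults = list(self.day_trajectory.get(stim, {}).values()) + [1.0]
                if resp.gain * max(mults) > 1.0 + 1e-12:
                    raise GeneratorError(
                        f"inhibitory gain for {stim.value} would drive the rate "
                        "negative (gain x day multiplier > 1)"
                    )

    def day_gain(self, stimulus: EpochLabel, day: int) -> float:
        resp = self.responses.get(stimulus)
        if resp is None:
            return 0.0
        return resp.gain * self.day_trajectory.get(stimulus, {}).get(day, 1.0)


def rate_function(
    profile: UnitResponseProfile, schedule: EventSchedule, times: np.ndarray
) -> np.ndarray:
    """Instantaneous firing rate (Hz) of the profile at the given times."""
    times = np.asarray(times, dtype=float)
    exc = np.zeros_like(times)
    inh = np.ones_like(times)
    day = schedule.day
    for stim, resp in profile.responses.items():
        g = profile.day_gain(stim, day)
        if g == 0.0:
            continue
        kern = resp.kernel
        support = kern.support_s()
        for ep in schedule.epochs_by_label(stim):
            t0 = ep.onset_s + resp.latency_s
            m = (times >= t0) & (times <= t0 + support)
            if not np.any(m):
                continue
            k = kern(times[m] - t0)
            if resp.sign == "excite":
                exc[m] += g * k
            else:
                inh[m] *= 1.0 - g * k
    return np.maximum(profile.baseline_rate_hz * (1.0 + exc) * inh, 0.0)


def _envelope_segments(
    profile: UnitResponseProfile, schedule: EventSchedule
) -> list[tuple[float, float, float]]:
    """Piecewise-constant upper bound of the rate, as (start, end, rate) spans."""
    total = schedule.duration_s
    edges = {0.0, total}
    bumps = []  # (start, end, excitatory gain contribution)
    day = schedule.day
    for stim, resp in profile.responses.items():
        g = profile.day_gain(stim, day)
        if g == 0.0 or resp.sign != "excite":
            continue
        support = resp.kernel.support_s()
        for ep in schedule.epochs_by_label(stim):
            s = ep.onset_s + resp.latency_s
            e = min(total, s + support)
            if e > s:
                bumps.append((s, e, g))
                edges.update((s, e))
    cuts = sorted(edges)
    base = profile.baseline_rate_hz
    segments = []
    for s, e in zip(cuts, cuts[1:]):
        mid = 0.5 * (s + e)
        gain = sum(g for bs, be, g in bumps if bs <= mid < be)
        segments.append((s, e, base * (1.0 + gain)))
    return segments


def simulate_unit(
    profile: UnitResponseProfile,
    schedule: EventSchedule,
    seed: int | None = 0,
    *,
    unit_id: str = "unit",
    genotype: Genotype = Genotype.CONTROL,
) -> SpikeTrain:
    """Sample one spike train by thinning against a piecewise-constant envelope.

    Candidate spikes are drawn from a homogeneous Poisson process at the local
    envelope rate (baseline outside kernel support, baseline x (1 + summed
    excitatory gains) within) and kept with probability rate(t)/envelope(t).
    Bit-identical output under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    spikes = []
    for start, end, env in _envelope_segments(profile, schedule):
        n = rng.poisson(env * (end - start))
        if n == 0:
            continue
        cand = np.sort(rng.uniform(start, end, size=n))
        accept = rng.uniform(0.0, env, size=n) < rate_function(profile, schedule, cand)
        spikes.append(cand[accept])
    ts = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
    # strictly-sorted invariant: drop exact duplicates (measure-zero event)
    if ts.size > 1:
        ts = np.concatenate(([ts[0]], ts[1:][np.diff(ts) > 0]))
    return SpikeTrain(
        unit_id=unit_id,
        timestamps_s=ts,
        genotype=genotype,
        day=schedule.day,
        session_id=schedule.session_id,
    )


PROFILE_CLASSES = (
    "us_activated",
    "us_inhibited",
    "cs_activated",
    "cs_inhibited",
    "non_responsive",
)


def control_like_trajectories() -> dict[str, dict[EpochLabel, dict[int, float]]]:
    """Day-dependent gain multipliers emulating intact plasticity.

    US-activated responses potentiate transiently (peak on day 2, back near
    day-1 level on day 3); CS+ activated responses grow monotonically across
    days; CS- inhibition weakens across days.  US-inhibited responses and
    CS- activated responses stay flat, matching their observed stability.
    """
    return {
        "us_activated": {EpochLabel.US: {1: 1.0, 2: 1.8, 3: 1.0}},
        "us_inhibited": {},
        "cs_activated": {EpochLabel.CS_PLUS: {1: 1.0, 2: 1.6, 3: 2.2}},
        "cs_inhibited": {EpochLabel.CS_MINUS: {1: 1.0, 2: 0.65, 3: 0.35}},
        "non_responsive": {},
    }


def ko_like_trajectories() -> dict[str, dict[EpochLabel, dict[int, float]]]:
    """Flat trajectories: every multiplier is 1 on every day."""
    return {cls: {} for cls in PROFILE_CLASSES}


# Response magnitudes are free parameters (reported only graphically in the
# literature); see docs/methods.md for the rationale behind these choices.
_CLASS_RESPONSES: dict[str, dict[EpochLabel, StimulusResponse]] = {
    "us_activated": {
        EpochLabel.US: StimulusResponse(6.0, "excite", 0.02, 0.01, 0.15)
    },
    "us_inhibited": {
        EpochLabel.US: StimulusResponse(0.8, "inhibit", 0.02, 0.01, 0.15)
    },
    "cs_activated": {
        EpochLabel.CS_PLUS: StimulusResponse(2.5, "excite", 0.05, 0.02, 0.30),
        EpochLabel.CS_MINUS: StimulusResponse(2.0, "excite", 0.05, 0.02, 0.30),
    },
    "cs_inhibited": {
        EpochLabel.CS_PLUS: StimulusResponse(0.6, "inhibit", 0.05, 0.02, 0.30),
        EpochLabel.CS_MINUS: StimulusResponse(0.7, "inhibit", 0.05, 0.02, 0.30),
    },
    "non_responsive": {},
}

DEFAULT_MIXTURE = {
    "us_activated": 0.30,
    "us_inhibited": 0.10,
    "cs_activated": 0.25,
    "cs_inhibited": 0.20,
    "non_responsive": 0.15,
}

BASELINE_RATE_RANGE_HZ = (1.0, 20.0)


def default_class_profiles(preset: str) -> dict[str, UnitResponseProfile]:
    """Template profile per class (baseline placeholder 5 Hz) for a preset."""
    traj = {"control_like": control_like_trajectories, "ko_like": ko_like_trajectories}
    if preset not in traj:
        raise GeneratorError(f"unknown preset {preset!r}")
    trajectories = traj[preset]()
    return {
        cls: UnitResponseProfile(
            baseline_rate_hz=5.0,
            responses=dict(_CLASS_RESPONSES[cls]),
            day_trajectory=trajectories[cls],
            profile_class=cls,
        )
        for cls in PROFILE_CLASSES
    }


@dataclass(frozen=True)
class CohortSpec:
    """Mixture specification for a simulated population of units."""

    n_units: int
    genotype: Genotype = Genotype.CONTROL
    preset: str = "control_like"
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 0:
            raise GeneratorError("n_units must be >= 0")
        w = np.array([self.weights.get(c, 0.0) for c in PROFILE_CLASSES])
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise GeneratorError("mixture weights must be >= 0 and sum to 1")


def simulate_cohort(
    spec: CohortSpec, schedules: list[EventSchedule]
) -> tuple[list[SpikeTrain], pd.DataFrame]:
    """Simulate a cohort across per-day schedules.

    Class counts come from one multinomial draw; each unit gets a baseline
    rate drawn log-uniformly on [1, 20] Hz and the preset's class template.
    Returns all spike trains (one per unit per day) and a ground-truth table
    with exactly one row per unit.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([spec.weights.get(c, 0.0) for c in PROFILE_CLASSES])
    counts = rng.multinomial(spec.n_units, weights)
    classes = [c for c, n in zip(PROFILE_CLASSES, counts) for _ in range(n)]
    lo, hi = BASELINE_RATE_RANGE_HZ
    baselines = np.exp(rng.uniform(math.log(lo), math.log(hi), size=spec.n_units))
    templates = default_class_profiles(spec.preset)

    trains: list[SpikeTrain] = []
    truth_rows = []
    for i, (cls, b) in enumerate(zip(classes, baselines)):
        unit_id = f"{spec.genotype.value.lower()}_u{i:03d}"
        profile = replace(templates[cls], baseline_rate_hz=float(b))
        for sched in schedules:
            unit_seed = int(rng.integers(0, 2**31 - 1))
            trains.append(
                simulate_unit(
                    profile,
                    sched,
                    seed=unit_seed,
                    unit_id=unit_id,
                    genotype=spec.genotype,
                )
            )
        resp = _CLASS_RESPONSES[cls]
        truth_rows.append(
            {
                "unit_id": unit_id,
                "class": cls,
                "genotype": spec.genotype.value,
                "baseline_rate_hz": float(b),
                "gain_us": resp.get(EpochLabel.US, StimulusResponse(0, "excite")).gain,
                "gain_csp": resp.get(
                    EpochLabel.CS_PLUS, StimulusResponse(0, "excite")
                ).gain,
                "gain_csm": resp.get(
                    EpochLabel.CS_MINUS, StimulusResponse(0, "excite")
                ).gain,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "unit_id",
            "class",
            "genotype",
            "baseline_rate_hz",
            "gain_us",
            "gain_csp",
            "gain_csm",
        ],
    )
    return trains, truth


@dataclass(frozen=True)
class Waveform:
    """One deterministic kinetic component of a sweep (peak-normalized)."""

    amplitude: float
    onset_s: float
    rise_s: float
    decay_s: float
    sign: float = 1.0


@dataclass(frozen=True)
class MiniAmplitudeModel:
    """Amplitude distribution of miniature events.

    ``lognormal``: exp(Normal(log(location), scale)); ``normal``:
    Normal(location, scale) truncated below at location/10.
    """

    family: str = "lognormal"
    location: float = 20.0
    scale: float = 0.3

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "lognormal":
            return np.exp(rng.normal(math.log(self.location), self.scale, size=n))
        if self.family == "normal":
            return np.maximum(
                rng.normal(self.location, self.scale, size=n), self.location / 10
            )
        raise GeneratorError(f"unknown amplitude family {self.family!r}")


@dataclass(frozen=True)
class TraceSpec:
    """Specification of one synthetic intracellular sweep."""

    sampling_rate_hz: float = 10_000.0
    duration_s: float = 1.0
    noise_sd: float = 0.0
    components: tuple[Waveform, ...] = ()
    mini_rate_hz: float = 0.0
    mini_amplitude: MiniAmplitudeModel = field(default_factory=MiniAmplitudeModel)
    mini_rise_s: float = 0.001
    mini_decay_s: float = 0.005
    mini_sign: float = -1.0
    modality: Modality = Modality.COMPOUND_PSP
    stimulus_onset_s: float | None = None
    cell_id: str = "cell"
    condition: Condition = Condition.NAIVE
    genotype: str = "CONTROL"

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise GeneratorError("sampling rate and duration must be > 0")
        if self.noise_sd < 0 or self.mini_rate_hz < 0:
            raise GeneratorError("noise_sd and mini_rate_hz must be >= 0")


def simulate_sweep(
    spec: TraceSpec, seed: int | None = 0
) -> tuple[SweepTrace, pd.DataFrame]:
    """Render a sweep: sum of components + Poisson minis + Gaussian noise.

    Returns the trace and a ground-truth event table (time_s, amplitude) for
    the injected minis.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.sampling_rate_hz))
    t = np.arange(n) / spec.sampling_rate_hz
    trace = np.zeros(n)
    for comp in spec.components:
        kern = DoeKernel(comp.rise_s, comp.decay_s)
        trace += comp.sign * comp.amplitude * kern(t - comp.onset_s)

    n_minis = rng.poisson(spec.mini_rate_hz * spec.duration_s)
    times = np.sort(rng.uniform(0.0, spec.duration_s, size=n_minis))
    amps = spec.mini_amplitude.draw(rng, n_minis)
    if n_minis:
        kern = DoeKernel(spec.mini_rise_s, spec.mini_decay_s)
        for t0, a in zip(times, amps):
            i0 = int(np.ceil(t0 * spec.sampling_rate_hz))
            i1 = min(n, i0 + int(kern.support_s() * spec.sampling_rate_hz) + 1)
            if i1 > i0:
                trace[i0:i1] += spec.mini_sign * a * kern(t[i0:i1] - t0)

    if spec.noise_sd > 0:
        trace = trace + rng.normal(0.0, spec.noise_sd, size=n)

    sweep = SweepTrace(
        samples=trace,
        sampling_rate_hz=spec.sampling_rate_hz,
        modality=spec.modality,
        stimulus_onset_s=spec.stimulus_onset_s,
        cell_id=spec.cell_id,
        condition=spec.condition,
        genotype=spec.genotype,
    )
    truth = pd.DataFrame({"time_s": times, "amplitude": amps})
    return sweep, truth
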