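"""Session timeline and shared domain types for the fear-conditioning protocol.

A conditioning session is a baseline period followed by randomly interleaved
CS+ and CS- trials.  Each CS+ cue co-terminates with a brief footshock (US);
each CS- is a flashing light that ends without shock.  Every trial is followed
by a long inter-trial interval (ITI).  Time is measured in seconds from session
start and every window is half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EpochLabel",
    "Genotype",
    "Epoch",
    "EventSchedule",
    "SpikeTrain",
    "TrialWindow",
    "ScheduleConfig",
    "InvalidConfigError",
    "ValidationError",
    "generate_schedule",
    "trials_from_schedule",
]


class EpochLabel(str, enum.Enum):
    BASELINE = "BASELINE"
    CS_PLUS = "CS_PLUS"
    CS_MINUS = "CS_MINUS"
    US = "US"
    ITI = "ITI"


class Genotype(str, enum.Enum):
    CONTROL = "CONTROL"
    KO = "KO"


class InvalidConfigError(ValueError):
    """A protocol configuration violates the trial-structure constraints."""


class ValidationError(ValueError):
    """Input data violate a structural invariant (named in the message)."""


@dataclass(frozen=True)
class Epoch:
    """One labelled span of the session timeline.

    ``trial_index`` numbers trials within their stimulus type (0-based); it is
    ``None`` for the baseline epoch.  CS- epochs carry the within-cue onsets of
    the light flashes in ``metadata['flash_onsets_s']``.
    """

    label: EpochLabel
    onset_s: float
    duration_s: float
    trial_index: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class EventSchedule:
    """Ordered timeline of baseline/CS+/CS-/US/ITI epochs for one session."""

    epochs: tuple[Epoch, ...]
    session_id: str = "session"
    day: int = 1

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValidationError(f"day must be >= 1, got {self.day}")
        onsets = [e.onset_s for e in self.epochs]
        if onsets != sorted(onsets):
            raise ValidationError("epochs must be sorted by onset")
        # Top-level epochs (everything but the nested US) must tile without
        # overlap; each US must lie inside a CS+ epoch and co-terminate with it.
        top = [e for e in self.epochs if e.label is not EpochLabel.US]
        for a, b in zip(top, top[1:]):
            if b.onset_s < a.end_s - 1e-9:
                raise ValidationError(
                    f"epochs {a.label.value}@{a.onset_s} and "
                    f"{b.label.value}@{b.onset_s} overlap"
                )
        cs_plus = [e for e in self.epochs if e.label is EpochLabel.CS_PLUS]
        for us in (e for e in self.epochs if e.label is EpochLabel.US):
            host = next(
                (c for c in cs_plus if c.onset_s <= us.onset_s and us.end_s <= c.end_s),
                None,
            )
            if host is None:
                raise ValidationError(f"US epoch at {us.onset_s}s lies outside any CS+")
            if us.end_s != host.end_s:
                raise ValidationError(
                    f"US at {us.onset_s}s must co-terminate with its CS+ "
                    f"(US ends {us.end_s}, CS+ ends {host.end_s})"
                )

    @property
    def duration_s(self) -> float:
        if not self.epochs:
            return 0.0
        return max(e.end_s for e in self.epochs)

    def epochs_by_label(self, label: EpochLabel) -> list[Epoch]:
        return [e for e in self.epochs if e.label is label]

    def n_trials(self, label: EpochLabel) -> int:
        return len(self.epochs_by_label(label))


@dataclass(frozen=True)
class SpikeTrain:
    """Timestamps of one sorted unit, with its cohort labels."""

    unit_id: str
    timestamps_s: np.ndarray
    genotype: Genotype = Genotype.CONTROL
    day: int = 1
    session_id: str = "session"

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps_s, dtype=float)
        object.__setattr__(self, "timestamps_s", ts)
        if ts.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: timestamps must be 1-D")
        if ts.size and ts[0] < 0:
            raise ValidationError(f"unit {self.unit_id}: negative timestamp {ts[0]}")
        if ts.size > 1 and np.any(np.diff(ts) <= 0):
            raise ValidationError(f"unit {self.unit_id}: timestamps not strictly sorted")

    def __len__(self) -> int:
        return int(self.timestamps_s.size)

    def count_in(self, start_s: float, end_s: float) -> int:
        """Spike count in the half-open window [start_s, end_s)."""
        lo, hi = np.searchsorted(self.timestamps_s, [start_s, end_s], side="left")
        return int(hi - lo)


@dataclass(frozen=True)
class TrialWindow:
    """An analysis window locked to one trial of one stimulus."""

    trial_index: int
    stimulus: EpochLabel
    onset_s: float
    duration_s: float
    include_iti: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("trial window duration must be > 0")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class ScheduleConfig:
    """Protocol parameters; defaults are the standard conditioning session.

    The default session is a 10 min baseline followed by 10 CS+ and 10 CS-
    trials in seeded random order, each a 10 s cue followed by a 110 s ITI.
    The CS+ ends with a 0.5 s footshock; the CS- flashes 5 times for 200 ms
    at 2 s intervals.  The CS- analysis window is aligned to the CS+ window
    (10 s) for comparability, with flash times kept as metadata.
    """

    n_cs_plus: int = 10
    n_cs_minus: int = 10
    cue_duration_s: float = 10.0
    us_duration_s: float = 0.5
    iti_duration_s: float = 110.0
    baseline_duration_s: float = 600.0
    n_flashes: int = 5
    flash_duration_s: float = 0.2
    flash_period_s: float = 2.0
    max_run_length: int = 3

    def __post_init__(self) -> None:
        if self.n_cs_plus < 0 or self.n_cs_minus < 0:
            raise InvalidConfigError("trial counts must be >= 0")
        for name in (
            "cue_duration_s",
            "us_duration_s",
            "iti_duration_s",
            "baseline_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if self.us_duration_s > self.cue_duration_s:
            raise InvalidConfigError("US cannot be longer than the cue")
        if self.max_run_length < 1:
            raise InvalidConfigError("max_run_length must be >= 1")

    @property
    def trial_block_s(self) -> float:
        return self.cue_duration_s + self.iti_duration_s

    @property
    def total_duration_s(self) -> float:
        n = self.n_cs_plus + self.n_cs_minus
        return self.baseline_duration_s + n * self.trial_block_s


# Behavioral sessions used a 2 min baseline; recordings used 10 min (default).
BEHAVIOR_CONFIG = ScheduleConfig(baseline_duration_s=120.0)


def _interleave(n_plus: int, n_minus: int, max_run: int, rng: np.random.Generator):
    """Random trial order with no more than ``max_run`` consecutive repeats."""
    while True:
        order = [EpochLabel.CS_PLUS] * n_plus + [EpochLabel.CS_MINUS] * n_minus
        rng.shuffle(order)
        run = 1
        ok = True
        for a, b in zip(order, order[1:]):
            run = run + 1 if a is b else 1
            if run > max_run:
                ok = False
                break
        if ok or n_plus == 0 or n_minus == 0:
            return order


def generate_schedule(
    config: ScheduleConfig | None = None,
    *,
    seed: int | None = 0,
    session_id: str = "session",
    day: int = 1,
) -> EventSchedule:
    """Build a session timeline from protocol parameters.

    Trial order is randomly interleaved under ``seed``; the same seed always
    yields the same order.  CS+ trials contain a US epoch co-terminating with
    the cue; CS- trials record flash onsets (0, 2, 4, ... s into the cue) as
    metadata.
    """
    config = config or ScheduleConfig()
    rng = np.random.default_rng(seed)
    order = _interleave(config.n_cs_plus, config.n_cs_minus, config.max_run_length, rng)

    epochs: list[Epoch] = [Epoch(EpochLabel.BASELINE, 0.0, config.baseline_duration_s)]
    t = config.baseline_duration_s
    counters = {EpochLabel.CS_PLUS: 0, EpochLabel.CS_MINUS: 0}
    flash_onsets = tuple(
        i * config.flash_period_s
        for i in range(config.n_flashes)
        if i * config.flash_period_s + config.flash_duration_s <= config.cue_duration_s
    )
    for label in order:
        idx = counters[label]
        counters[label] += 1
        meta = {} if label is EpochLabel.CS_PLUS else {"flash_onsets_s": flash_onsets}
        epochs.append(Epoch(label, t, config.cue_duration_s, idx, meta))
        if label is EpochLabel.CS_PLUS:
            us_onset = t + config.cue_duration_s - config.us_duration_s
            epochs.append(Epoch(EpochLabel.US, us_onset, config.us_duration_s, idx))
        t += config.cue_duration_s
        epochs.append(Epoch(EpochLabel.ITI, t, config.iti_duration_s, idx))
        t += config.iti_duration_s
    return EventSchedule(tuple(epochs), session_id=session_id, day=day)


def trials_from_schedule(
    schedule: EventSchedule,
    stimulus: EpochLabel | str,
    include_iti: bool = False,
) -> list[TrialWindow]:
    """Extract analysis windows for one stimulus type, in temporal order.

    With ``include_iti`` each window runs through the ITI that follows the
    trial, as used for the concatenated trial+ITI population analysis.
    """
    stimulus = EpochLabel(stimulus)
    if stimulus in (EpochLabel.BASELINE, EpochLabel.ITI):
        raise ValidationError(f"{stimulus.value} is not a trial stimulus")
    itis = schedule.epochs_by_label(EpochLabel.ITI)
    windows = []
    for ep in schedule.epochs_by_label(stimulus):
        duration = ep.duration_s
        if include_iti:
            nxt = next((i for i in itis if abs(i.onset_s - ep.end_s) < 1e-9), None)
            if nxt is None and stimulus is EpochLabel.US:
                # the US sits inside its CS+, whose end starts the ITI
                nxt = next((i for i in itis if i.onset_s >= ep.end_s - 1e-9), None)
            if nxt is not None:
                duration = nxt.end_s - ep.onset_s
        windows.append(
            TrialWindow(
                trial_index=ep.trial_index if ep.trial_index is not None else 0,
                stimulus=stimulus,
                onset_s=ep.onset_s,
                duration_s=duration,
                include_iti=include_iti,
            )
        )
    return windows
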