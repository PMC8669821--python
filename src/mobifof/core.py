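"""Core containers shared across the mobifof pipeline.

The package works on 6-axis inertial recordings from a sensor worn on the
lower back.  Signals are kept in the *sensor frame*; the mapping between
sensor axes and anatomical directions (vertical, medio-lateral,
antero-posterior) travels with the recording, and the true vertical is
re-estimated from gravity by the detection layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: gravitational acceleration used throughout (m/s^2); a resting upright
#: sensor reads +G on its vertical accelerometer axis.
G = 9.81

#: canonical anatomical axis names
ANATOMICAL_AXES = ("antero_posterior", "medio_lateral", "vertical")

#: default axis convention: column 0 = AP, column 1 = ML, column 2 = vertical
DEFAULT_AXIS_CONVENTION = {"antero_posterior": 0, "medio_lateral": 1, "vertical": 2}


class MobifofError(Exception):
    """Base class for structured pipeline failures."""


@dataclass
class IMURecording:
    """A timestamped 6-axis inertial signal with sensor metadata.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz (128 Hz for lab sessions, 100 Hz default
        for daily recordings).
    acc : ndarray of shape (n, 3)
        Acceleration in m/s^2, sensor frame. Includes gravity.
    gyro : ndarray of shape (n, 3)
        Angular velocity in deg/s, sensor frame.
    sensor_site : str
        One of ``lower_back``, ``left_foot``, ``right_foot``.
    axis_convention : dict
        Maps anatomical axis names to sensor-frame column indices.
    markers : dict
        Optional named segments ``{name: (start_s, end_s)}`` — lab sessions
        carry test markers (``tug``, ``sts_normal``, ``sts_fast``).
    """

    sample_rate: float
    acc: np.ndarray
    gyro: np.ndarray
    sensor_site: str = "lower_back"
    start_time: float = 0.0
    axis_convention: dict = field(default_factory=lambda: dict(DEFAULT_AXIS_CONVENTION))
    markers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.acc.shape != self.gyro.shape or self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc and gyro must both have shape (n, 3)")
        if np.isnan(self.acc).any() or np.isnan(self.gyro).any():
            raise ValueError("recording contains NaN samples")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def axis(self, name: str) -> int:
        return self.axis_convention[name]

    def slice(self, start_s: float, end_s: float) -> "IMURecording":
        """Return the sub-recording covering [start_s, end_s)."""
        i0 = max(0, int(np.floor(start_s * self.sample_rate)))
        i1 = min(self.n_samples, int(np.ceil(end_s * self.sample_rate)))
        return IMURecording(
            sample_rate=self.sample_rate,
            acc=self.acc[i0:i1],
            gyro=self.gyro[i0:i1],
            sensor_site=self.sensor_site,
            start_time=self.start_time + i0 / self.sample_rate,
            axis_convention=dict(self.axis_convention),
        )


# ---------------------------------------------------------------------------
# ground-truth timeline (generator output, oracle for recovery tests)
# ---------------------------------------------------------------------------

@dataclass
class TrueBout:
    start: float
    end: float
    per_second_speed: np.ndarray  # m/s, one value per whole elapsed second

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TrueTransition:
    start: float
    end: float
    peak_power: float | None = None  # W, sit-to-stand only


@dataclass
class TrueTurn:
    start: float
    end: float
    angle: float       # deg, signed about vertical
    peak_omega: float  # deg/s, absolute

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class GroundTruthTimeline:
    """Event annotation emitted alongside every synthetic recording."""

    duration: float
    walking_bouts: list = field(default_factory=list)
    sit_to_stands: list = field(default_factory=list)
    stand_to_sits: list = field(default_factory=list)
    turns: list = field(default_factory=list)

    def validate(self) -> None:
        for events in (self.walking_bouts, self.sit_to_stands,
                       self.stand_to_sits, self.turns):
            prev_end = -np.inf
            for ev in sorted(events, key=lambda e: e.start):
                if ev.start < prev_end:
                    raise ValueError("overlapping events within one category")
                if ev.start < 0 or ev.end > self.duration + 1e-9:
                    raise ValueError("event outside recording span")
                prev_end = ev.end


# ---------------------------------------------------------------------------
# detected events
# ---------------------------------------------------------------------------

@dataclass
class WalkingBout:
    """A retained locomotion episode (>= 15 s, every second >= 0.2 m/s)."""

    start: float
    end: float
    per_second_speed: np.ndarray
    unreliable: bool = False  # cadence outside [0.4, 3.5] steps/s somewhere

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class PosturalTransition:
    kind: str  # "sit_to_stand" | "stand_to_sit"
    start: float
    end: float
    peak_power: float | None = None  # W, sit_to_stand only

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("transition end must exceed start")
        if self.kind == "sit_to_stand" and self.peak_power is not None and self.peak_power <= 0:
            raise ValueError("peak_power must be > 0")


@dataclass
class TurnEvent:
    start: float
    end: float
    angle: float       # deg, signed
    peak_omega: float  # deg/s, absolute

    @property
    def duration(self) -> float:
        return self.end - self.start


def events_to_table(timeline_or_events, categories=None):
    """Flatten events into (category, start_s, end_s, value) rows.

    ``value`` is per-category: mean speed for bouts, peak power for
    sit-to-stands, peak angular velocity for turns, NaN otherwise.
    """
    import pandas as pd

    rows = []
    if isinstance(timeline_or_events, GroundTruthTimeline):
        groups = {
            "walking_bout": timeline_or_events.walking_bouts,
            "sit_to_stand": timeline_or_events.sit_to_stands,
            "stand_to_sit": timeline_or_events.stand_to_sits,
            "turn": timeline_or_events.turns,
        }
    else:
        groups = timeline_or_events
    for cat, events in groups.items():
        if categories is not None and cat not in categories:
            continue
        for ev in events:
            if cat == "walking_bout":
                val = float(np.mean(ev.per_second_speed)) if len(ev.per_second_speed) else np.nan
            elif cat == "sit_to_stand":
                val = np.nan if ev.peak_power is None else float(ev.peak_power)
            elif cat == "turn":
                val = float(ev.peak_omega)
            else:
                val = np.nan
            rows.append((cat, float(ev.start), float(ev.end), val))
    return pd.DataFrame(rows, columns=["category", "start_s", "end_s", "value"])
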