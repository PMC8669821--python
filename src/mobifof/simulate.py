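"""Synthetic lower-back IMU cohort generator.

Emulates the study conditions of a two-group Parkinson's cohort (with /
without fear of falling, FOF+/FOF-): instrumented lab sessions (timed-up-
and-go at 128 Hz, five-times-sit-to-stand twice) and multi-day free-living
recordings, with full ground-truth event annotation so every downstream
stage is testable without patient data.

Signals are built from smooth kinematic templates:

* postural transitions — a minimum-jerk vertical displacement of the trunk
  whose height is solved so that the true vertical peak power
  ``m * (a_v + g) * v_v`` hits the drawn target, plus a forward-and-back
  trunk-pitch excursion on the medio-lateral gyro axis;
* turns — a ``sin^2`` yaw-rate pulse whose integral is the signed turn
  angle;
* gait — vertical and antero-posterior oscillation at a cadence consistent
  with the true per-second speed through an inverted-pendulum step model
  (step length ``2*sqrt(2*l*h - h^2)`` with pendulum length ``0.53*height``).

Gravity is present on the vertical accelerometer axis (+9.81 m/s^2 at
rest); a small random static tilt of the sensor and additive Gaussian
noise complete the measurement model.  All randomness flows from one
explicit seed.

For cohort-scale statistics a *timeline-only* fast path skips raw-signal
synthesis and returns the ground-truth event timelines directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import (
    G,
    DEFAULT_AXIS_CONVENTION,
    GroundTruthTimeline,
    IMURecording,
    TrueBout,
    TrueTransition,
    TrueTurn,
)

# column indices in the body frame (same as the default axis convention)
_AP, _ML, _V = 0, 1, 2

#: pendulum length as a fraction of body height (inverted-pendulum model)
LEG_FRACTION = 0.53

#: classes of walking-bout duration, seconds (half-open, partitioning [15, inf))
BOUT_CLASS_EDGES = {"SWB": (15.0, 30.0), "MWB": (30.0, 60.0), "LWB": (60.0, float("inf"))}


# ---------------------------------------------------------------------------
# phenotype specification
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSpec:
    """Generative targets for one synthetic subject.

    ``gait_speed_mode1`` / ``gait_speed_mode2`` are the two preferred
    daily-life walking speeds (the modes of the pooled speed
    distribution); ``mode_mix_weight`` is the fraction of walking seconds
    drawn around mode 1.  ``turn_peak_omega_mean`` drives the lab TUG
    turns; home turns are slower by ``home_turn_omega_scale`` (their peak
    angular velocities are drawn log-normally, matching the long right
    tail of free-living turning).
    """

    group_label: str = "FOF-"          # "FOF+" or "FOF-"
    fes_i: int = 17
    updrs_iii: int = 22
    gender: str = "female"             # "male" | "female"
    body_mass: float = 77.0            # kg
    height: float = 1.75               # m
    gait_speed_mode1: float = 0.63     # m/s
    gait_speed_mode2: float = 0.96     # m/s
    mode_mix_weight: float = 0.45
    turn_peak_omega_mean: float = 160.0  # deg/s (lab turns)
    turn_peak_omega_sd: float = 22.0
    sts_peak_power_mean: float = 20.0  # W (home sit-to-stands)
    sts_peak_power_sd: float = 12.0
    bouts_per_day_by_class: tuple = (34.0, 6.0, 8.0)  # expected SWB, MWB, LWB
    sts_per_hour: float = 4.5
    turns_per_hour: float = 100.0
    wear_hours_per_day: float = 12.0
    # secondary knobs (defaults chosen once for the emulated cohort)
    home_turn_omega_scale: float = 0.40   # home turn median / lab turn mean
    home_turn_omega_median: float | None = None  # deg/s; overrides the scale
    lab_power_scale: float = 2.0          # lab STS power / home STS power
    tug_gait_speed: float | None = None   # m/s; default 1.18 * mode2
    speed_jitter_sd: float = 0.08         # within-bout per-second speed sd

    def __post_init__(self) -> None:
        self.validate()

    @property
    def lab_gait_speed(self) -> float:
        return self.tug_gait_speed if self.tug_gait_speed is not None else 1.18 * self.gait_speed_mode2

    def validate(self) -> None:
        if self.group_label not in ("FOF+", "FOF-"):
            raise ValueError(f"group_label must be 'FOF+' or 'FOF-', got {self.group_label!r}")
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be 'male' or 'female', got {self.gender!r}")
        if not self.gait_speed_mode1 < self.gait_speed_mode2:
            raise ValueError("gait_speed_mode1 must be < gait_speed_mode2")
        if not 0.0 <= self.mode_mix_weight <= 1.0:
            raise ValueError("mode_mix_weight must lie in [0, 1]")
        for name in ("sts_per_hour", "turns_per_hour", "wear_hours_per_day",
                     "turn_peak_omega_sd", "sts_peak_power_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(b < 0 for b in self.bouts_per_day_by_class):
            raise ValueError("bouts_per_day_by_class entries must be >= 0")
        if self.body_mass <= 0 or self.height <= 0:
            raise ValueError("body_mass and height must be > 0")
        if self.fes_i < 16:
            raise ValueError("FES-I total score cannot be below 16")
        has_fof = self.fes_i > 19
        if has_fof != (self.group_label == "FOF+"):
            raise ValueError(
                f"FES-I {self.fes_i} inconsistent with group {self.group_label} "
                "(FOF+ is defined by FES-I > 19)"
            )


def default_phenotype(group: str = "FOF-", **overrides) -> PhenotypeSpec:
    """Cohort-typical phenotype for one group (FOF+ mobility is reduced)."""
    if group == "FOF+":
        base = dict(
            group_label="FOF+", fes_i=25, updrs_iii=30, gender="female",
            body_mass=81.0, height=1.78,
            gait_speed_mode1=0.49, gait_speed_mode2=0.91, mode_mix_weight=0.55,
            turn_peak_omega_mean=120.0, turn_peak_omega_sd=22.0,
            sts_peak_power_mean=20.0, sts_peak_power_sd=12.0,
            bouts_per_day_by_class=(26.0, 4.5, 6.0),
            sts_per_hour=3.7, turns_per_hour=86.0, wear_hours_per_day=12.0,
        )
    elif group == "FOF-":
        base = dict(group_label="FOF-")
    else:
        raise ValueError("group must be 'FOF+' or 'FOF-'")
    base.update(overrides)
    return PhenotypeSpec(**base)


@dataclass
class GroupEffectConfig:
    """Mean shifts applied to FOF+ subjects relative to the FOF- base,
    plus between-subject scatter shared by both groups.

    The default direction and magnitudes mirror the emulated effect
    pattern: markedly slower lab turns, moderately lower first-mode gait
    speed, and somewhat fewer walking bouts, transitions and turns per
    hour in the FOF+ group — lab capacity differences larger than
    daily-life performance differences.  ``home_omega_transfer`` controls
    how much of the lab turning deficit carries over into (submaximal)
    daily-life turning.
    """

    turn_omega_shift: float = -40.0   # deg/s (lab turns)
    mode1_shift: float = -0.07        # m/s
    mode2_shift: float = -0.03        # m/s
    bout_scale: float = 0.87          # multiplies expected bout counts
    sts_rate_shift: float = -0.5      # per hour
    turns_rate_shift: float = -12.0   # per hour
    home_omega_transfer: float = 0.25  # fraction of lab deficit seen at home
    # between-subject standard deviations
    omega_between_sd: float = 18.0
    mode1_between_sd: float = 0.10
    mode2_between_sd: float = 0.08
    bout_between_cv: float = 0.25
    rate_between_cv: float = 0.20
    home_omega_between_cv: float = 0.08

    @classmethod
    def zero(cls) -> "GroupEffectConfig":
        """Null configuration: the two groups are exchangeable."""
        return cls(turn_omega_shift=0.0, mode1_shift=0.0, mode2_shift=0.0,
                   bout_scale=1.0, sts_rate_shift=0.0, turns_rate_shift=0.0)


# ---------------------------------------------------------------------------
# kinematic templates
# ---------------------------------------------------------------------------

def _min_jerk_profiles(h: float, T: float, t: np.ndarray):
    """Displacement/velocity/acceleration of a minimum-jerk rise of height
    ``h`` over duration ``T`` evaluated at times ``t`` in [0, T]."""
    tau = np.clip(t / T, 0.0, 1.0)
    s = h * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    v = h / T * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    a = h / T**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)
    return s, v, a


def _sts_peak_power(h: float, T: float, mass: float) -> float:
    tau = np.linspace(0.0, 1.0, 400)
    _, v, a = _min_jerk_profiles(h, T, tau * T)
    return float(np.max(mass * (a + G) * v))


def solve_rise_height(peak_power: float, T: float, mass: float) -> float:
    """Height of a minimum-jerk rise whose vertical peak power
    ``m*(a_v+g)*v_v`` equals ``peak_power``."""
    f = lambda h: _sts_peak_power(h, T, mass) - peak_power
    return brentq(f, 1e-5, 2.0, xtol=1e-8)


def cadence_for_speed(speed: float) -> float:
    """Step frequency (steps/s) used by the generator for a given speed."""
    return float(np.clip(1.35 + 0.5 * speed, 0.6, 3.2))


def rise_height_for_step(step_length: float, pendulum_length: float) -> float:
    """Vertical excursion of the inverted pendulum for one step."""
    half = step_length / 2.0
    if half >= pendulum_length:
        raise ValueError("step length incompatible with pendulum length")
    return pendulum_length - math.sqrt(pendulum_length**2 - half**2)


# ---------------------------------------------------------------------------
# signal assembly
# ---------------------------------------------------------------------------

class _SignalCanvas:
    """Mutable body-frame dynamic signal on a fixed sample grid."""

    def __init__(self, duration: float, fs: float):
        self.fs = fs
        self.n = int(round(duration * fs))
        self.acc = np.zeros((self.n, 3))   # dynamic (gravity-free) accel, m/s^2
        self.gyro = np.zeros((self.n, 3))  # deg/s

    def _span(self, start: float, dur: float):
        i0 = int(round(start * self.fs))
        i1 = min(self.n, i0 + int(round(dur * self.fs)))
        t = (np.arange(i1 - i0)) / self.fs
        return i0, i1, t

    def add_transition(self, start: float, T: float, h: float, upward: bool,
                       pitch_max_deg: float = 22.0) -> None:
        i0, i1, t = self._span(start, T)
        _, v, a = _min_jerk_profiles(h if upward else -h, T, t)
        self.acc[i0:i1, _V] += a
        # forward lean and back: pitch angle theta_max*sin^2(pi t/T)
        self.gyro[i0:i1, _ML] += pitch_max_deg * (math.pi / T) * np.sin(2 * math.pi * t / T)

    def add_turn(self, start: float, T: float, angle_deg: float) -> float:
        """sin^2 yaw pulse integrating to ``angle_deg``; returns peak omega."""
        i0, i1, t = self._span(start, T)
        omega_pk = 2.0 * angle_deg / T  # deg/s, signed
        self.gyro[i0:i1, _V] += omega_pk * np.sin(math.pi * t / T) ** 2
        return abs(omega_pk)

    def add_gait(self, start: float, duration: float, per_second_speed: np.ndarray,
                 height: float) -> None:
        i0, i1, t = self._span(start, duration)
        if i1 <= i0:
            return
        # piecewise-constant per-second speed, extended over a partial last second
        sec = np.minimum(t.astype(int), len(per_second_speed) - 1)
        v = per_second_speed[sec]
        f = np.clip(1.35 + 0.5 * v, 0.6, 3.2)
        phase = np.cumsum(f) / self.fs
        ell = LEG_FRACTION * height
        step = v / f
        half = np.minimum(step / 2.0, 0.95 * ell)
        h = ell - np.sqrt(ell**2 - half**2)
        # vertical oscillation with displacement amplitude h/2 at cadence f
        self.acc[i0:i1, _V] += -(h / 2.0) * (2 * math.pi * f) ** 2 * np.sin(2 * math.pi * phase)
        self.acc[i0:i1, _AP] += (0.5 + 0.8 * v) * np.sin(2 * math.pi * phase + 1.0)
        # small pelvic wobble, well below the turn threshold
        self.gyro[i0:i1, _ML] += 3.0 * np.sin(2 * math.pi * phase + 0.5)
        self.gyro[i0:i1, _V] += 3.0 * np.sin(2 * math.pi * phase + 2.1)

    def to_recording(self, rng: np.random.Generator, sample_rate: float,
                     noise_acc: float, noise_gyro: float, tilt_deg: float,
                     markers: dict | None = None) -> IMURecording:
        acc_body = self.acc.copy()
        acc_body[:, _V] += G  # accelerometer measures reaction to gravity
        rot = _tilt_rotation(tilt_deg, rng)
        acc = acc_body @ rot.T
        gyro = self.gyro @ rot.T
        if noise_acc > 0:
            acc = acc + rng.normal(0.0, noise_acc, acc.shape)
        if noise_gyro > 0:
            gyro = gyro + rng.normal(0.0, noise_gyro, gyro.shape)
        return IMURecording(sample_rate=sample_rate, acc=acc, gyro=gyro,
                            axis_convention=dict(DEFAULT_AXIS_CONVENTION),
                            markers=markers or {})


def _tilt_rotation(tilt_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation about a random horizontal axis by ``tilt_deg`` degrees."""
    if tilt_deg == 0:
        return np.eye(3)
    phi = rng.uniform(0, 2 * math.pi)
    axis = np.array([math.cos(phi), math.sin(phi), 0.0])
    ang = math.radians(tilt_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)


# ---------------------------------------------------------------------------
# lab session
# ---------------------------------------------------------------------------

LAB_SAMPLE_RATE = 128.0  # Hz


def _truncated_normal(rng, mean, sd, low, high=np.inf):
    for _ in range(100):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high if np.isfinite(high) else mean))


def generate_lab_session(spec: PhenotypeSpec, seed: int, *, synthesize: bool = True,
                         noise_acc: float = 0.04, noise_gyro: float = 0.4,
                         tilt_deg: float | None = None,
                         sts_cycles: int = 5):
    """One lab session: TUG, then normal-speed 5xSTS, then fast 5xSTS.

    Returns ``(IMURecording at 128 Hz, GroundTruthTimeline)``; with
    ``synthesize=False`` the recording is ``None`` (timeline-only fast
    path).  The recording carries segment markers ``tug``, ``sts_normal``
    and ``sts_fast``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    tl = GroundTruthTimeline(duration=0.0)
    segments: dict[str, tuple[float, float]] = {}

    plan: list[tuple] = []  # (kind, start, duration, payload)
    t = 3.0  # initial rest

    # ----- TUG -----
    tug_start = t - 1.0
    p_tug = _truncated_normal(rng, spec.sts_peak_power_mean * spec.lab_power_scale,
                              spec.sts_peak_power_sd, 5.0)
    T_sist = 1.5
    plan.append(("sist", t, T_sist, p_tug)); t += T_sist + 0.8

    v_lab = spec.lab_gait_speed
    for leg in range(2):
        walk_dur = 7.0 / v_lab
        n_sec = max(1, int(walk_dur))
        speeds = np.clip(rng.normal(v_lab, 0.05, n_sec), 0.3, None)
        plan.append(("walk", t, walk_dur, speeds)); t += walk_dur + 0.3
        if leg == 0:
            omega1 = _truncated_normal(rng, spec.turn_peak_omega_mean,
                                       spec.turn_peak_omega_sd, 60.0)
            T1 = 2 * 180.0 / omega1
            plan.append(("turn", t, T1, 180.0)); t += T1 + 0.3
    # turn-to-sit: 180 deg turn overlapping the stand-to-sit
    omega2 = _truncated_normal(rng, 0.93 * spec.turn_peak_omega_mean,
                               spec.turn_peak_omega_sd, 50.0)
    T2 = 2 * 180.0 / omega2
    plan.append(("turn", t, T2, -180.0))
    stsi_start = t + 0.4
    T_stsi = 1.6
    plan.append(("stsi", stsi_start, T_stsi, None))
    t = max(t + T2, stsi_start + T_stsi)
    segments["tug"] = (tug_start, t + 1.0)
    t += 5.0  # rest

    # ----- 5xSTS blocks -----
    for variant, scale, pscale in (("sts_normal", 1.0, 1.0), ("sts_fast", 0.62, 1.35)):
        block_start = t - 1.0
        for _ in range(sts_cycles):
            jit = rng.uniform(0.92, 1.08)
            Tu = 1.5 * scale * jit
            power = _truncated_normal(
                rng, spec.sts_peak_power_mean * spec.lab_power_scale * pscale,
                spec.sts_peak_power_sd, 5.0)
            plan.append(("sist", t, Tu, power)); t += Tu + 0.7 * scale
            Td = 1.5 * scale * jit
            plan.append(("stsi", t, Td, None)); t += Td + 0.7 * scale
        segments[variant] = (block_start, t + 1.0)
        t += 5.0

    total = t + 2.0
    tl.duration = total

    canvas = _SignalCanvas(total, LAB_SAMPLE_RATE) if synthesize else None
    for kind, start, dur, payload in plan:
        if kind == "sist":
            tl.sit_to_stands.append(TrueTransition(start, start + dur, payload))
            if canvas is not None:
                h = solve_rise_height(payload, dur, spec.body_mass)
                canvas.add_transition(start, dur, h, upward=True)
        elif kind == "stsi":
            tl.stand_to_sits.append(TrueTransition(start, start + dur))
            if canvas is not None:
                canvas.add_transition(start, dur, 0.25, upward=False)
        elif kind == "turn":
            peak = abs(2.0 * payload / dur)
            tl.turns.append(TrueTurn(start, start + dur, payload, peak))
            if canvas is not None:
                canvas.add_turn(start, dur, payload)
        elif kind == "walk":
            tl.walking_bouts.append(TrueBout(start, start + dur, payload))
            if canvas is not None:
                canvas.add_gait(start, dur, payload, spec.height)
    tl.validate()

    rec = None
    if canvas is not None:
        tilt = rng.uniform(0.0, 8.0) if tilt_deg is None else tilt_deg
        rec = canvas.to_recording(rng, LAB_SAMPLE_RATE, noise_acc, noise_gyro,
                                  tilt, markers=segments)
    return rec, tl


# ---------------------------------------------------------------------------
# daily recordings
# ---------------------------------------------------------------------------

def _place_intervals(rng, durations, wear, occupied, margin):
    """Uniformly place non-overlapping intervals; returns placed spans."""
    placed = []
    for dur in durations:
        for _ in range(200):
            s = rng.uniform(0.0, max(wear - dur, 1e-6))
            iv = (s - margin, s + dur + margin)
            if all(iv[1] <= a or iv[0] >= b for a, b in occupied):
                occupied.append((iv[0], iv[1]))
                placed.append((s, s + dur))
                break
    return placed


def _place_spaced(rng, durations, wear, margin):
    """Place all intervals at once, mutually non-overlapping, by drawing
    uniform spacings into the free time (O(n log n))."""
    durations = np.asarray(durations, float)
    n = len(durations)
    if n == 0:
        return []
    order = rng.permutation(n)
    occupied_time = durations[order] + margin
    free = wear - float(occupied_time.sum())
    if free <= 0:  # day denser than feasible; fall back to sequential packing
        free = 0.0
    gaps = np.sort(rng.uniform(0.0, free, n))
    starts = gaps + np.concatenate([[0.0], np.cumsum(occupied_time[:-1])])
    spans = [(float(s), float(s + durations[order][i])) for i, s in enumerate(starts)]
    inv = np.empty(n, int)
    inv[order] = np.arange(n)
    return [spans[inv[i]] for i in range(n)]


def generate_day_timeline(spec: PhenotypeSpec, rng: np.random.Generator,
                          wear_hours: float | None = None) -> GroundTruthTimeline:
    """Ground-truth event timeline for one wear day (no signal)."""
    wh = spec.wear_hours_per_day if wear_hours is None else wear_hours
    wear = wh * 3600.0 * rng.uniform(0.97, 1.03)
    tl = GroundTruthTimeline(duration=wear)

    # walking bouts per class
    durs = []
    for cls, expected in zip(("SWB", "MWB", "LWB"), spec.bouts_per_day_by_class):
        k = rng.poisson(expected)
        lo, hi = BOUT_CLASS_EDGES[cls]
        for _ in range(k):
            if cls == "LWB":
                durs.append(min(60.0 + rng.exponential(45.0), 600.0))
            else:
                durs.append(rng.uniform(lo, hi))
    occupied: list[tuple[float, float]] = []
    for s, e in _place_intervals(rng, durs, wear, occupied, margin=3.0):
        n_sec = int(e - s)
        mode = (spec.gait_speed_mode1 if rng.random() < spec.mode_mix_weight
                else spec.gait_speed_mode2)
        speeds = np.clip(rng.normal(mode, spec.speed_jitter_sd, n_sec), 0.25, 2.5)
        tl.walking_bouts.append(TrueBout(s, e, speeds))

    # postural transitions (Poisson, kept clear of bouts)
    trans_occ = list(occupied)
    n_sist = rng.poisson(spec.sts_per_hour * wear / 3600.0)
    for s, e in _place_intervals(rng, rng.uniform(1.2, 1.8, n_sist), wear,
                                 trans_occ, margin=2.0):
        power = _truncated_normal(rng, spec.sts_peak_power_mean, spec.sts_peak_power_sd, 5.0)
        tl.sit_to_stands.append(TrueTransition(s, e, power))
    n_stsi = rng.poisson(spec.sts_per_hour * wear / 3600.0)
    for s, e in _place_intervals(rng, rng.uniform(1.2, 1.8, n_stsi), wear,
                                 trans_occ, margin=2.0):
        tl.stand_to_sits.append(TrueTransition(s, e))

    # turns (may coincide with gait, as in daily life; mutually disjoint)
    n_turns = rng.poisson(spec.turns_per_hour * wear / 3600.0)
    med = (spec.home_turn_omega_median if spec.home_turn_omega_median is not None
           else spec.home_turn_omega_scale * spec.turn_peak_omega_mean)
    turn_durs, turn_angles = [], []
    for _ in range(n_turns):
        for _ in range(30):
            omega = med * math.exp(rng.normal(0.0, 0.36))
            angle = rng.uniform(50.0, 200.0) * rng.choice([-1.0, 1.0])
            T = 2 * abs(angle) / omega
            if 0.5 <= T <= 10.0:
                turn_durs.append(T); turn_angles.append(angle)
                break
    placed = _place_spaced(rng, turn_durs, wear, margin=1.0)
    for (s, e), angle in zip(placed, turn_angles):
        T = e - s
        tl.turns.append(TrueTurn(s, e, angle, abs(2 * angle / T)))

    for cat in ("walking_bouts", "sit_to_stands", "stand_to_sits", "turns"):
        getattr(tl, cat).sort(key=lambda ev: ev.start)
    tl.validate()
    return tl


def synthesize_day(tl: GroundTruthTimeline, spec: PhenotypeSpec,
                   rng: np.random.Generator, sample_rate: float = 100.0,
                   noise_acc: float = 0.04, noise_gyro: float = 0.4,
                   tilt_deg: float | None = None) -> IMURecording:
    """Render a day timeline into a raw sensor signal."""
    canvas = _SignalCanvas(tl.duration, sample_rate)
    for ev in tl.sit_to_stands:
        h = solve_rise_height(ev.peak_power, ev.end - ev.start, spec.body_mass)
        canvas.add_transition(ev.start, ev.end - ev.start, h, upward=True)
    for ev in tl.stand_to_sits:
        canvas.add_transition(ev.start, ev.end - ev.start, 0.25, upward=False)
    for ev in tl.turns:
        canvas.add_turn(ev.start, ev.end - ev.start, ev.angle)
    for b in tl.walking_bouts:
        canvas.add_gait(b.start, b.end - b.start, b.per_second_speed, spec.height)
    tilt = rng.uniform(0.0, 8.0) if tilt_deg is None else tilt_deg
    return canvas.to_recording(rng, sample_rate, noise_acc, noise_gyro, tilt)


def generate_daily_recording(spec: PhenotypeSpec, n_days: int, seed: int, *,
                             synthesize: bool = True, sample_rate: float = 100.0,
                             wear_hours: float | None = None,
                             noise_acc: float = 0.04, noise_gyro: float = 0.4,
                             tilt_deg: float | None = None):
    """Multi-day free-living recordings: list of ``(IMURecording | None,
    GroundTruthTimeline)``, one per day."""
    spec.validate()
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    out = []
    root = np.random.SeedSequence(seed)
    for day_seq in root.spawn(n_days):
        rng = np.random.default_rng(day_seq)
        tl = generate_day_timeline(spec, rng, wear_hours=wear_hours)
        rec = None
        if synthesize:
            rec = synthesize_day(tl, spec, rng, sample_rate=sample_rate,
                                 noise_acc=noise_acc, noise_gyro=noise_gyro,
                                 tilt_deg=tilt_deg)
        out.append((rec, tl))
    return out


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    subject_id: str
    spec: PhenotypeSpec
    lab_recording: IMURecording | None
    lab_timeline: GroundTruthTimeline
    daily: list  # list of (IMURecording | None, GroundTruthTimeline)


def _draw_subject_spec(group: str, cfg: GroupEffectConfig,
                       rng: np.random.Generator) -> PhenotypeSpec:
    base = default_phenotype("FOF-")
    pos = group == "FOF+"
    mode1 = rng.normal(base.gait_speed_mode1 + (cfg.mode1_shift if pos else 0.0),
                       cfg.mode1_between_sd)
    mode2 = rng.normal(base.gait_speed_mode2 + (cfg.mode2_shift if pos else 0.0),
                       cfg.mode2_between_sd)
    mode1 = float(np.clip(mode1, 0.30, None))
    mode2 = float(np.clip(mode2, mode1 + 0.15, None))
    omega = rng.normal(base.turn_peak_omega_mean + (cfg.turn_omega_shift if pos else 0.0),
                       cfg.omega_between_sd)
    # daily-life turning is submaximal: only part of the lab deficit
    # transfers, with its own between-subject scatter
    home_omega = (base.home_turn_omega_scale
                  * (base.turn_peak_omega_mean
                     + cfg.home_omega_transfer * (omega - base.turn_peak_omega_mean))
                  * rng.lognormal(0.0, cfg.home_omega_between_cv))
    scale = cfg.bout_scale if pos else 1.0
    bouts = tuple(max(0.5, scale * b * rng.lognormal(0.0, cfg.bout_between_cv))
                  for b in base.bouts_per_day_by_class)
    sts_rate = max(0.3, (base.sts_per_hour + (cfg.sts_rate_shift if pos else 0.0))
                   * rng.lognormal(0.0, cfg.rate_between_cv))
    turn_rate = max(5.0, (base.turns_per_hour + (cfg.turns_rate_shift if pos else 0.0))
                    * rng.lognormal(0.0, cfg.rate_between_cv))
    return PhenotypeSpec(
        group_label=group,
        fes_i=int(rng.integers(20, 41)) if pos else int(rng.integers(16, 20)),
        updrs_iii=int(np.clip(rng.normal(30 if pos else 22, 6), 5, 60)),
        gender="female" if rng.random() < (0.8 if pos else 0.7) else "male",
        body_mass=float(np.clip(rng.normal(80.0, 10.0), 45.0, 130.0)),
        height=float(np.clip(rng.normal(1.76, 0.07), 1.45, 2.05)),
        gait_speed_mode1=mode1,
        gait_speed_mode2=mode2,
        mode_mix_weight=float(np.clip(rng.normal(0.5, 0.08), 0.15, 0.85)),
        turn_peak_omega_mean=float(np.clip(omega, 70.0, None)),
        turn_peak_omega_sd=base.turn_peak_omega_sd,
        home_turn_omega_median=float(np.clip(home_omega, 25.0, None)),
        sts_peak_power_mean=float(np.clip(rng.normal(20.0, 5.0), 8.0, None)),
        sts_peak_power_sd=base.sts_peak_power_sd,
        bouts_per_day_by_class=bouts,
        sts_per_hour=sts_rate,
        turns_per_hour=turn_rate,
        wear_hours_per_day=base.wear_hours_per_day,
    )


def generate_cohort(n_fof_pos: int, n_fof_neg: int,
                    group_effect_config: GroupEffectConfig | None = None,
                    seed: int = 0, *, n_days: int = 14,
                    synthesize: bool = False,
                    wear_hours: float | None = None) -> list:
    """Draw a two-group cohort; returns a list of :class:`SubjectData`.

    With ``synthesize=False`` (default) only ground-truth timelines are
    produced — the fast path used for cohort-level statistics.
    """
    if n_fof_pos < 1 or n_fof_neg < 1:
        raise ValueError("cohort sizes must be >= 1")
    cfg = group_effect_config or GroupEffectConfig()
    root = np.random.SeedSequence(seed)
    groups = ["FOF+"] * n_fof_pos + ["FOF-"] * n_fof_neg
    subjects = []
    for i, (group, seq) in enumerate(zip(groups, root.spawn(len(groups)))):
        child = seq.spawn(3)
        spec = _draw_subject_spec(group, cfg, np.random.default_rng(child[0]))
        lab_seed = int(np.random.default_rng(child[1]).integers(0, 2**31 - 1))
        lab_rec, lab_tl = generate_lab_session(spec, lab_seed, synthesize=synthesize)
        daily_seed = int(np.random.default_rng(child[2]).integers(0, 2**31 - 1))
        daily = generate_daily_recording(spec, n_days, daily_seed,
                                         synthesize=synthesize,
                                         wear_hours=wear_hours)
        subjects.append(SubjectData(subject_id=f"S{i + 1:03d}", spec=spec,
                                    lab_recording=lab_rec, lab_timeline=lab_tl,
                                    daily=daily))
    return subjects
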