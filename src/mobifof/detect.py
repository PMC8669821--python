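"""Event detection from a lower-back 6-axis inertial recording.

Transparent, testable detectors for the three event families the analysis
needs:

* walking bouts with per-second gait speed (band-pass step-frequency
  energy gating + an inverted-pendulum speed model),
* sit-to-stand / stand-to-sit postural transitions with vertical peak
  power (trunk-pitch excursion coincident with a biphasic vertical
  acceleration pattern),
* turns with peak yaw angular velocity (thresholded, integrated yaw
  rate about the estimated vertical axis).

Free-living retention rules: per-second speeds below 0.2 m/s are treated
as non-gait, surviving contiguous runs shorter than 15 s are discarded,
and turns are kept only with durations of 0.5-10 s and angles > 45 deg.
All time intervals are half-open ``[start, end)``; inclusion at exactly
0.2 m/s uses ``>=``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .core import G, IMURecording, MobifofError, PosturalTransition, TurnEvent, WalkingBout
from .simulate import LEG_FRACTION

# paper-default retention thresholds
MIN_BOUT_DURATION_S = 15.0
MIN_GAIT_SPEED_MS = 0.2
TURN_MIN_ANGLE_DEG = 45.0
TURN_DURATION_RANGE_S = (0.5, 10.0)

# detector tuning (configurable, not prescribed by the emulated protocol)
TURN_ENTRY_THRESHOLD_DPS = 15.0
TURN_EXIT_THRESHOLD_DPS = 5.0
TURN_MERGE_GAP_S = 0.2
GAIT_BAND_HZ = (0.5, 3.0)
GAIT_ENERGY_THRESHOLD_MS2 = 0.15  # combined band RMS
CADENCE_RANGE_SPS = (0.4, 3.5)


class NoGravityError(MobifofError):
    """Raised when no usable gravity vector is present in the signal."""


# ---------------------------------------------------------------------------
# frame estimation
# ---------------------------------------------------------------------------

def estimate_vertical_axis(rec: IMURecording) -> np.ndarray:
    """Unit direction of vertical (gravity) in the sensor frame.

    Low-pass gravity over quiescent epochs (little rotation, acceleration
    magnitude near g).  Falls back, with a warning, to the whole-recording
    mean when no quiescent epoch exists.
    """
    if rec.duration < 5.0:
        raise ValueError("recording must be at least 5 s long")
    fs = rec.sample_rate
    b, a = sps.butter(2, 0.25 / (fs / 2), btype="low")
    acc_lp = sps.filtfilt(b, a, rec.acc, axis=0)
    b1, a1 = sps.butter(2, 1.0 / (fs / 2), btype="low")
    gyro_mag = sps.filtfilt(b1, a1, np.linalg.norm(rec.gyro, axis=1))
    acc_norm = np.linalg.norm(sps.filtfilt(b1, a1, rec.acc, axis=0), axis=1)
    quiet = (gyro_mag < 5.0) & (np.abs(acc_norm - G) < 0.5)
    if quiet.sum() >= fs:  # at least one second of quiescence
        mean_vec = acc_lp[quiet].mean(axis=0)
    else:
        warnings.warn("no quiescent epoch found; using whole-recording mean gravity")
        mean_vec = acc_lp.mean(axis=0)
    norm = np.linalg.norm(mean_vec)
    if norm < 0.5 * G:
        raise NoGravityError("no gravity component found in accelerometer signal")
    return mean_vec / norm


@dataclass
class _Frame:
    """Anatomical signal components resolved against the estimated vertical."""

    fs: float
    acc_v: np.ndarray    # vertical acceleration incl. gravity, m/s^2
    acc_ap: np.ndarray   # antero-posterior acceleration, m/s^2
    yaw: np.ndarray      # angular velocity about vertical, deg/s
    pitch: np.ndarray    # angular velocity about medio-lateral, deg/s


def resolve_frame(rec: IMURecording, v_axis: np.ndarray | None = None) -> _Frame:
    v = estimate_vertical_axis(rec) if v_axis is None else np.asarray(v_axis, float)
    v = v / np.linalg.norm(v)

    def _horizontal(name):
        e = np.zeros(3)
        e[rec.axis(name)] = 1.0
        e = e - (e @ v) * v
        return e / np.linalg.norm(e)

    ml = _horizontal("medio_lateral")
    ap = _horizontal("antero_posterior")
    return _Frame(fs=rec.sample_rate,
                  acc_v=rec.acc @ v, acc_ap=rec.acc @ ap,
                  yaw=rec.gyro @ v, pitch=rec.gyro @ ml)


def _lowpass(x, fs, fc, order=2):
    b, a = sps.butter(order, fc / (fs / 2), btype="low")
    return sps.filtfilt(b, a, x)


def _highpass(x, fs, fc, order=2):
    b, a = sps.butter(order, fc / (fs / 2), btype="high")
    return sps.filtfilt(b, a, x)


def _bandpass(x, fs, band, order=2):
    b, a = sps.butter(order, [band[0] / (fs / 2), band[1] / (fs / 2)], btype="band")
    return sps.filtfilt(b, a, x)


def _runs(mask: np.ndarray):
    """Start/stop indices (half-open) of True runs."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


# ---------------------------------------------------------------------------
# gait
# ---------------------------------------------------------------------------

def locomotion_candidates(rec: IMURecording, frame: _Frame | None = None,
                          min_duration: float = 4.0,
                          energy_threshold: float = GAIT_ENERGY_THRESHOLD_MS2):
    """Candidate locomotion intervals ``(start_s, end_s)`` from band-pass
    step-frequency energy on the vertical and AP acceleration."""
    fr = frame or resolve_frame(rec)
    fs = fr.fs
    bv = _bandpass(fr.acc_v, fs, GAIT_BAND_HZ)
    bap = _bandpass(fr.acc_ap, fs, GAIT_BAND_HZ)
    win = max(1, int(fs))
    kernel = np.ones(win) / win
    energy = np.sqrt(np.convolve(bv**2 + bap**2, kernel, mode="same"))
    mask = energy > energy_threshold
    # merge sub-second dropouts
    gap = int(fs)
    out = []
    for i0, i1 in _runs(mask):
        if out and i0 - out[-1][1] <= gap:
            out[-1] = (out[-1][0], i1)
        else:
            out.append((i0, i1))
    return [(i0 / fs, i1 / fs) for i0, i1 in out if (i1 - i0) / fs >= min_duration]


def estimate_instantaneous_speed(rec: IMURecording, start_s: float, end_s: float,
                                 height: float = 1.75,
                                 frame: _Frame | None = None) -> np.ndarray:
    """Per-second gait speed over ``[start_s, end_s)``.

    Step events come from AP-acceleration peaks; step length from an
    inverted-pendulum model on the drift-corrected, double-integrated
    vertical displacement and subject height; speed = step length x step
    rate, averaged on a one-second grid anchored at ``start_s`` (the final
    partial second is dropped).  Seconds whose cadence falls outside
    0.4-3.5 steps/s are returned as NaN (flagged unreliable).
    """
    fr = frame or resolve_frame(rec)
    fs = fr.fs
    i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
    i0, i1 = max(0, i0), min(len(fr.acc_v), i1)
    n_sec = int((i1 - i0) / fs)
    if n_sec < 1:
        return np.empty(0)

    ap = _bandpass(fr.acc_ap[i0:i1], fs, GAIT_BAND_HZ)
    rms = float(np.sqrt(np.mean(ap**2))) or 1e-9
    peaks, _ = sps.find_peaks(ap, distance=max(1, int(0.28 * fs)), prominence=0.3 * rms)
    step_times = peaks / fs  # relative to start_s

    # vertical displacement: HP -> integrate -> HP -> integrate -> HP
    az = _highpass(fr.acc_v[i0:i1], fs, 0.3)
    vz = _highpass(cumulative_trapezoid(az, dx=1 / fs, initial=0.0), fs, 0.3)
    z = _highpass(cumulative_trapezoid(vz, dx=1 / fs, initial=0.0), fs, 0.3)

    ell = LEG_FRACTION * height
    speeds = np.full(n_sec, np.nan)
    for k in range(n_sec):
        in_win = step_times[(step_times >= k - 0.5) & (step_times < k + 1.5)]
        if len(in_win) < 2:
            continue
        f = 1.0 / float(np.mean(np.diff(in_win)))
        if not (CADENCE_RANGE_SPS[0] <= f <= CADENCE_RANGE_SPS[1]):
            continue  # unreliable cadence
        zs = z[int(k * fs):int((k + 1) * fs)]
        h = 2.0 * math.sqrt(2.0) * float(np.std(zs))
        h = min(h, ell)  # pendulum geometry cap
        step_len = 2.0 * math.sqrt(max(2.0 * ell * h - h * h, 0.0))
        speeds[k] = step_len * f
    return speeds


def apply_bout_filters(per_second_speed: np.ndarray,
                       min_speed: float = MIN_GAIT_SPEED_MS,
                       min_duration: float = MIN_BOUT_DURATION_S):
    """Compose the free-living retention rules on a per-second speed series.

    Seconds with speed < ``min_speed`` (or NaN) are removed; surviving
    contiguous runs shorter than ``min_duration`` seconds are discarded.
    Returns ``[(offset_s, speeds), ...]``.  Idempotent by construction.
    """
    v = np.asarray(per_second_speed, float)
    keep = np.where(np.isnan(v), False, v >= min_speed)
    return [(int(a), v[a:b]) for a, b in _runs(keep) if b - a >= min_duration]


def detect_walking_bouts(rec: IMURecording, height: float = 1.75,
                         frame: _Frame | None = None,
                         min_speed: float = MIN_GAIT_SPEED_MS,
                         min_duration: float = MIN_BOUT_DURATION_S) -> list:
    """Retained walking bouts (>= 15 s, every second >= 0.2 m/s)."""
    if rec.duration < min_duration:
        return []
    fr = frame or resolve_frame(rec)
    bouts = []
    for c0, c1 in locomotion_candidates(rec, fr):
        speeds = estimate_instantaneous_speed(rec, c0, c1, height=height, frame=fr)
        for off, run in apply_bout_filters(speeds, min_speed, min_duration):
            bouts.append(WalkingBout(start=c0 + off, end=c0 + off + len(run),
                                     per_second_speed=run))
    return bouts


# ---------------------------------------------------------------------------
# postural transitions
# ---------------------------------------------------------------------------

def detect_postural_transitions(rec: IMURecording, body_mass: float,
                                frame: _Frame | None = None,
                                min_pitch_deg: float = 10.0) -> list:
    """Sit-to-stand / stand-to-sit transitions with vertical peak power.

    Candidates are excursions of the integrated trunk-pitch angle; the
    kind follows the sign of the dominant vertical velocity (up =
    sit-to-stand); peak power = ``m * (a_v + g) * v_v`` maximised over the
    transition, with the vertical velocity drift-corrected to rest at the
    window edges.
    """
    if body_mass is None or body_mass <= 0:
        raise ValueError("body_mass (kg) must be provided and > 0")
    fr = frame or resolve_frame(rec)
    fs = fr.fs
    pitch = _lowpass(fr.pitch, fs, 5.0)
    # segment on the pitch-rate RMS envelope (robust to baseline drift of
    # the integrated angle during repeated-cycle blocks)
    win = max(1, int(0.25 * fs))
    kernel = np.ones(win) / win
    envelope = np.sqrt(np.convolve(pitch**2, kernel, mode="same"))
    regions = []
    for i0, i1 in _runs(envelope > 4.0):
        if regions and (i0 - regions[-1][1]) / fs <= 0.1:
            regions[-1] = (regions[-1][0], i1)
        else:
            regions.append((i0, i1))

    acc_lp = _lowpass(fr.acc_v, fs, 5.0)
    out = []
    for i0, i1 in regions:
        # require a genuine trunk-pitch excursion, not gait wobble
        theta = cumulative_trapezoid(pitch[i0:i1], dx=1 / fs, initial=0.0)
        if not len(theta) or np.max(np.abs(theta)) < min_pitch_deg:
            continue
        # the centered RMS window expands each edge by ~win/2; compensate
        shrink = int(0.45 * win)
        if i1 - i0 > 2 * shrink + 2:
            i0, i1 = i0 + shrink, i1 - shrink
        pad = int(0.3 * fs)
        w0, w1 = max(0, i0 - pad), min(len(pitch), i1 + pad)
        a_dyn = acc_lp[w0:w1] - G
        vz = cumulative_trapezoid(a_dyn, dx=1 / fs, initial=0.0)
        vz = vz - np.linspace(0.0, vz[-1], len(vz))  # rest at both edges
        if len(vz) < 2:
            continue
        k = int(np.argmax(np.abs(vz)))
        upward = vz[k] > 0
        kind = "sit_to_stand" if upward else "stand_to_sit"
        power = None
        if upward:
            power = float(body_mass * np.max((a_dyn + G) * vz))
            if power <= 0:
                continue
        out.append(PosturalTransition(kind=kind, start=i0 / fs, end=i1 / fs,
                                      peak_power=power))
    out.sort(key=lambda e: e.start)
    return out


# ---------------------------------------------------------------------------
# turns
# ---------------------------------------------------------------------------

def detect_turns(rec: IMURecording, frame: _Frame | None = None,
                 entry_threshold: float = TURN_ENTRY_THRESHOLD_DPS,
                 exit_threshold: float = TURN_EXIT_THRESHOLD_DPS,
                 merge_gap: float = TURN_MERGE_GAP_S,
                 min_angle: float = TURN_MIN_ANGLE_DEG,
                 duration_range: tuple = TURN_DURATION_RANGE_S) -> list:
    """Turns about the vertical axis: yaw-rate excursions whose integrated
    angle exceeds ``min_angle`` deg with duration inside
    ``duration_range`` seconds."""
    fr = frame or resolve_frame(rec)
    fs = fr.fs
    yaw = _lowpass(fr.yaw, fs, 3.0)
    mag = np.abs(yaw)

    core = _runs(mag > entry_threshold)
    # extend each core interval out to the exit threshold or a sign change
    intervals = []
    for i0, i1 in core:
        sign = np.sign(yaw[(i0 + i1) // 2]) or 1.0
        while i0 > 0 and mag[i0 - 1] > exit_threshold and np.sign(yaw[i0 - 1]) == sign:
            i0 -= 1
        while i1 < len(yaw) and mag[min(i1, len(yaw) - 1)] > exit_threshold \
                and np.sign(yaw[min(i1, len(yaw) - 1)]) == sign:
            i1 += 1
        intervals.append([i0, i1, sign])

    # merge same-direction fragments separated by less than the merge gap
    merged = []
    for iv in intervals:
        if merged and iv[2] == merged[-1][2] and (iv[0] - merged[-1][1]) / fs <= merge_gap:
            merged[-1][1] = max(merged[-1][1], iv[1])
        elif merged and iv[0] < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv[1])
        else:
            merged.append(list(iv))

    def _tail(idx, inward):
        """Extrapolate the (locally quadratic) yaw tail to its zero."""
        k = max(1, int(0.08 * fs))
        j = min(max(idx, 0), len(mag) - 1)
        jin = min(max(idx + inward * k, 0), len(mag) - 1)
        slope = abs(mag[jin] - mag[j]) / (k / fs)
        if slope <= 0:
            return 0.0
        return min(2.0, 2.0 * mag[j] / slope)

    out = []
    for i0, i1, _ in merged:
        t0 = i0 / fs - _tail(i0, +1)
        t1 = (i1 - 1) / fs + _tail(i1 - 1, -1)
        dur = t1 - t0
        if not (duration_range[0] <= dur <= duration_range[1]):
            continue
        angle = float(np.trapezoid(yaw[i0:i1], dx=1 / fs))
        if abs(angle) <= min_angle:
            continue
        out.append(TurnEvent(start=t0, end=t1, angle=angle,
                             peak_omega=float(np.max(mag[i0:i1]))))
    return out
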