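"""Instrumented lab tests: timed-up-and-go (TUG) and five-times-sit-to-stand.

A TUG session yields the start of the sit-to-stand ``t_b_SiSt``, the peak
powers and turn peak angular velocities, the end of the stand-to-sit
``t_e_StSi`` and of the second turn ``t_e_Turn2``, the mean gait speed of
the test ``V_TUG_avg``, and the total time

    T_TUG = max(t_e_StSi, t_e_Turn2) - t_b_SiSt.

A 5xSTS attempt yields its total time (first sit-to-stand onset to the
completion of the fifth rise) and the mean of the five per-cycle vertical
peak powers.  Lab recordings carry segment markers written by the
simulator; auto-segmentation of unmarked sessions is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GroundTruthTimeline, IMURecording, MobifofError
from . import detect

#: the nine lab parameters, in canonical column order
LAB_FEATURES = ["T_TUG", "V_TUG_avg", "omega_TUG_1", "omega_TUG_2", "P_TUG",
                "T_5xSTS_N", "P_5xSTS_N", "T_5xSTS_F", "P_5xSTS_F"]


class LabAnalysisError(MobifofError):
    """A required test component was not found in the recording."""


@dataclass
class TUGResult:
    t_b_SiSt: float
    t_e_StSi: float
    t_e_Turn2: float
    T_TUG: float
    V_TUG_avg: float
    omega_TUG_1: float
    omega_TUG_2: float
    P_TUG: float

    def __post_init__(self) -> None:
        expected = max(self.t_e_StSi, self.t_e_Turn2) - self.t_b_SiSt
        if abs(self.T_TUG - expected) > 1e-9:
            raise ValueError("T_TUG must equal max(t_e_StSi, t_e_Turn2) - t_b_SiSt")
        if self.T_TUG <= 0 or self.omega_TUG_1 <= 0 or self.omega_TUG_2 <= 0:
            raise ValueError("TUG durations and angular velocities must be > 0")


@dataclass
class FiveSTSResult:
    variant: str          # "normal" | "fast"
    total_time: float     # s
    mean_peak_power: float  # W

    def __post_init__(self) -> None:
        if self.variant not in ("normal", "fast"):
            raise ValueError("variant must be 'normal' or 'fast'")
        if self.total_time <= 0 or self.mean_peak_power <= 0:
            raise ValueError("total_time and mean_peak_power must be > 0")


def _marker_slice(rec: IMURecording, name: str) -> IMURecording:
    if name not in rec.markers:
        raise LabAnalysisError(f"recording has no '{name}' segment marker")
    s, e = rec.markers[name]
    return rec.slice(max(0.0, s), min(rec.duration, e))


def analyze_tug(rec: IMURecording, body_mass: float, height: float) -> TUGResult:
    """Extract the eight TUG parameters from a marked lab recording."""
    seg = _marker_slice(rec, "tug") if "tug" in rec.markers else rec
    frame = detect.resolve_frame(seg)

    transitions = detect.detect_postural_transitions(seg, body_mass, frame=frame)
    sists = [t for t in transitions if t.kind == "sit_to_stand"]
    stsis = [t for t in transitions if t.kind == "stand_to_sit"]
    if not sists:
        raise LabAnalysisError("sit-to-stand not found")
    if not stsis:
        raise LabAnalysisError("stand-to-sit not found")

    turns = detect.detect_turns(seg, frame=frame)
    if len(turns) < 2:
        raise LabAnalysisError("turn 2 not found" if len(turns) == 1 else "turn 1 not found")

    sist = sists[0]
    t_b = sist.start
    t_e_stsi = stsis[-1].end
    turn1, turn2 = turns[0], turns[1]

    # mean per-second gait speed over the locomotion phases of the test
    end_of_test = max(t_e_stsi, turn2.end)
    speeds = []
    for c0, c1 in detect.locomotion_candidates(seg, frame, min_duration=3.5):
        if c1 <= t_b or c0 >= end_of_test:
            continue
        v = detect.estimate_instantaneous_speed(seg, c0, c1, height=height, frame=frame)
        speeds.extend(v[~np.isnan(v)])
    if not speeds:
        raise LabAnalysisError("walking phase not found")

    return TUGResult(
        t_b_SiSt=t_b,
        t_e_StSi=t_e_stsi,
        t_e_Turn2=turn2.end,
        T_TUG=max(t_e_stsi, turn2.end) - t_b,
        V_TUG_avg=float(np.mean(speeds)),
        omega_TUG_1=turn1.peak_omega,
        omega_TUG_2=turn2.peak_omega,
        P_TUG=sist.peak_power,
    )


def analyze_5xsts(rec: IMURecording, body_mass: float, variant: str = "normal",
                  n_cycles: int = 5) -> FiveSTSResult:
    """Total time and mean per-cycle peak power of one 5xSTS attempt."""
    marker = {"normal": "sts_normal", "fast": "sts_fast"}.get(variant)
    if marker is None:
        raise ValueError("variant must be 'normal' or 'fast'")
    seg = _marker_slice(rec, marker) if marker in rec.markers else rec
    transitions = detect.detect_postural_transitions(seg, body_mass)
    sists = [t for t in transitions if t.kind == "sit_to_stand"]
    if len(sists) != n_cycles:
        raise LabAnalysisError(
            f"expected {n_cycles} sit-to-stand cycles, detected {len(sists)}")
    total = sists[-1].end - sists[0].start
    mean_power = float(np.mean([t.peak_power for t in sists]))
    return FiveSTSResult(variant=variant, total_time=total, mean_peak_power=mean_power)


def analyze_lab_session(rec: IMURecording, body_mass: float, height: float) -> dict:
    """All nine lab parameters of a marked session as a flat dict."""
    tug = analyze_tug(rec, body_mass, height)
    normal = analyze_5xsts(rec, body_mass, "normal")
    fast = analyze_5xsts(rec, body_mass, "fast")
    return {
        "T_TUG": tug.T_TUG, "V_TUG_avg": tug.V_TUG_avg,
        "omega_TUG_1": tug.omega_TUG_1, "omega_TUG_2": tug.omega_TUG_2,
        "P_TUG": tug.P_TUG,
        "T_5xSTS_N": normal.total_time, "P_5xSTS_N": normal.mean_peak_power,
        "T_5xSTS_F": fast.total_time, "P_5xSTS_F": fast.mean_peak_power,
    }


def lab_result_from_timeline(tl: GroundTruthTimeline) -> dict:
    """Lab parameters computed directly from a ground-truth timeline.

    Used on the timeline-only fast path, where the event times and values
    are exact; the arithmetic (the T_TUG formula, the 5xSTS endpoints and
    power means) is identical to the signal path.
    """
    sists = tl.sit_to_stands
    stsis = tl.stand_to_sits
    turns = tl.turns
    if len(sists) < 11 or len(turns) < 2 or not stsis:
        raise LabAnalysisError("timeline does not contain a full lab session")
    tug_sist, tug_stsi = sists[0], stsis[0]
    turn1, turn2 = turns[0], turns[1]
    speeds = np.concatenate([b.per_second_speed for b in tl.walking_bouts[:2]])
    t_tug = max(tug_stsi.end, turn2.end) - tug_sist.start
    res = {
        "T_TUG": t_tug, "V_TUG_avg": float(np.mean(speeds)),
        "omega_TUG_1": turn1.peak_omega, "omega_TUG_2": turn2.peak_omega,
        "P_TUG": tug_sist.peak_power,
    }
    for variant, block in (("N", sists[1:6]), ("F", sists[6:11])):
        res[f"T_5xSTS_{variant}"] = block[-1].end - block[0].start
        res[f"P_5xSTS_{variant}"] = float(np.mean([t.peak_power for t in block]))
    return res
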