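"""Daily-life aggregation: from per-day event tables to the 32 home
mobility parameters.

For each subject, days with less than 6 h of measurement are discarded;
the rest contribute (i) per-day quantities — walking percent overall and
per bout class, sit-to-stands and turns per hour — summarised as
min/avg/max over days, and (ii) pooled distributions over all days
stacked together — per-second gait speed (overall and per bout class),
sit-to-stand vertical peak power, turn peak angular velocity — summarised
as median (P50) and 95th percentile (P95), plus the two modes of the
pooled speed distribution from a two-component Gaussian mixture.

Walking bouts are classed by duration into short (SWB, [15, 30) s),
medium (MWB, [30, 60) s) and long (LWB, >= 60 s) — half-open intervals so
the classes partition [15, inf).  Percentiles use linear interpolation on
the pooled sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .core import GroundTruthTimeline, MobifofError, PosturalTransition, TurnEvent, WalkingBout
from .detect import apply_bout_filters

MIN_WEAR_HOURS = 6.0
BOUT_CLASSES = ("SWB", "MWB", "LWB")

#: the 32 home-derived parameters, in canonical column order
HOME_FEATURES = (
    ["V_ALL_P50", "V_ALL_P95", "V_mu1", "V_mu2",
     "Gait_ALL_min", "Gait_ALL_avg", "Gait_ALL_max"]
    + [f"V_{c}_{q}" for c in BOUT_CLASSES for q in ("P50", "P95")]
    + [f"Gait_{c}_{s}" for c in BOUT_CLASSES for s in ("min", "avg", "max")]
    + ["P_H_P50", "P_H_P95", "SiSt_min", "SiSt_avg", "SiSt_max",
       "omega_H_P50", "omega_H_P95", "Turns_min", "Turns_avg", "Turns_max"]
)


class NoValidDaysError(MobifofError):
    """Every wear day of a subject fell below the 6 h validity threshold."""


class TooFewSamplesError(MobifofError):
    """Not enough pooled samples for a distribution summary."""


@dataclass
class DayEvents:
    """Retained events of one wear day."""

    wear_hours: float
    bouts: list = field(default_factory=list)        # WalkingBout
    sit_to_stands: list = field(default_factory=list)  # PosturalTransition
    turns: list = field(default_factory=list)          # TurnEvent

    @classmethod
    def from_timeline(cls, tl: GroundTruthTimeline) -> "DayEvents":
        """Build a day record from generator ground truth, applying the
        same retention rules the detector applies."""
        bouts = []
        for b in tl.walking_bouts:
            for off, run in apply_bout_filters(b.per_second_speed):
                bouts.append(WalkingBout(start=b.start + off,
                                         end=b.start + off + len(run),
                                         per_second_speed=run))
        sists = [PosturalTransition("sit_to_stand", t.start, t.end, t.peak_power)
                 for t in tl.sit_to_stands]
        turns = [TurnEvent(t.start, t.end, t.angle, t.peak_omega) for t in tl.turns]
        return cls(wear_hours=tl.duration / 3600.0, bouts=bouts,
                   sit_to_stands=sists, turns=turns)


def filter_valid_days(days: list, min_hours: float = MIN_WEAR_HOURS) -> list:
    """Keep days with wear time >= ``min_hours`` (phases of less than 6 h
    are discarded); raise when no day survives."""
    valid = [d for d in days if d.wear_hours >= min_hours]
    if not valid:
        raise NoValidDaysError(
            f"no day reaches {min_hours} h of wear time ({len(days)} days supplied)")
    return valid


def classify_bout(bout: WalkingBout) -> str:
    """SWB for [15, 30) s, MWB for [30, 60) s, LWB for >= 60 s."""
    dur = bout.duration + 1e-9  # tolerate float round-off at class edges
    if dur < 15.0:
        raise ValueError("bouts shorter than 15 s are excluded upstream")
    if dur < 30.0:
        return "SWB"
    if dur < 60.0:
        return "MWB"
    return "LWB"


def daily_walking_percent(day: DayEvents, bout_class: str = "ALL") -> float:
    """Walking time in a class as percent of the day's measurement time."""
    total = sum(b.duration for b in day.bouts
                if bout_class == "ALL" or classify_bout(b) == bout_class)
    return 100.0 * total / (day.wear_hours * 3600.0)


def min_avg_max_over_days(per_day_values) -> tuple:
    vals = np.asarray(list(per_day_values), float)
    if vals.size < 1:
        raise ValueError("need at least one valid day")
    return float(vals.min()), float(vals.mean()), float(vals.max())


def pooled_distribution_stats(samples, stats=(50, 95), min_samples: int = 20) -> tuple:
    """Percentiles (linear interpolation) of the pooled all-days sample."""
    x = np.asarray(list(samples), float)
    if x.size == 0:
        raise TooFewSamplesError("empty pooled sample")
    if x.size < min_samples:
        warnings.warn(f"pooled sample has only {x.size} values (low n)")
    return tuple(float(np.percentile(x, q)) for q in stats)


def events_per_hour(day: DayEvents, category: str) -> float:
    events = {"sit_to_stand": day.sit_to_stands, "turn": day.turns}[category]
    return len(events) / day.wear_hours


# ---------------------------------------------------------------------------
# bimodal gait-speed model
# ---------------------------------------------------------------------------

@dataclass
class BimodalFit:
    v_mu1: float
    v_mu2: float
    degenerate: bool
    weights: tuple
    means: tuple
    sds: tuple


def fit_bimodal_modes(speed_samples, seed: int = 0, min_samples: int = 100,
                      max_samples: int = 4000, n_restarts: int = 10,
                      min_weight: float = 0.05, min_separation: float = 0.05) -> BimodalFit:
    """First and second modes of the pooled gait-speed distribution.

    A two-component Gaussian mixture (free variances) is fitted by EM with
    ``n_restarts`` quantile-spread initialisations; modes are the sorted
    component means.  A degenerate fit (component weight < 0.05 or means
    closer than 0.05 m/s) returns the plain sample mode for both values
    with the ``degenerate`` flag set.  Large pools are thinned to
    ``max_samples`` by even subsampling (order-independent).
    """
    x = np.sort(np.asarray(list(speed_samples), float))
    if x.size < min_samples:
        raise TooFewSamplesError(
            f"need >= {min_samples} speed samples for the mixture fit, got {x.size}")
    if x.size > max_samples:
        x = x[np.linspace(0, x.size - 1, max_samples).astype(int)]
    X = x.reshape(-1, 1)

    spreads = np.linspace(5, 45, n_restarts)  # percent around the median
    best = None
    for i, spread in enumerate(spreads):
        means_init = np.percentile(x, [50 - spread, 50 + spread]).reshape(-1, 1)
        gm = GaussianMixture(n_components=2, covariance_type="full",
                             means_init=means_init, weights_init=[0.5, 0.5],
                             reg_covar=1e-6, max_iter=200,
                             random_state=seed + i)
        gm.fit(X)
        score = gm.score(X)
        if best is None or score > best[0]:
            best = (score, gm)
    gm = best[1]
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    weights = gm.weights_.ravel()[order]
    sds = np.sqrt(gm.covariances_.reshape(-1)[order])

    degenerate = weights.min() < min_weight or (means[1] - means[0]) < min_separation
    if not degenerate:
        # a genuine second mode requires a density dip between the means
        grid = np.linspace(means[0], means[1], 64)
        pdf = lambda t: (weights[0] * np.exp(-0.5 * ((t - means[0]) / sds[0])**2) / sds[0]
                         + weights[1] * np.exp(-0.5 * ((t - means[1]) / sds[1])**2) / sds[1])
        if pdf(grid).min() >= 0.95 * min(pdf(means[0]), pdf(means[1])):
            degenerate = True
    if degenerate:
        hist, edges = np.histogram(x, bins=40)
        mode = float((edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2)
        return BimodalFit(mode, mode, True, tuple(weights), tuple(means), tuple(sds))
    return BimodalFit(float(means[0]), float(means[1]), False,
                      tuple(weights), tuple(means), tuple(sds))


# ---------------------------------------------------------------------------
# full daily feature set
# ---------------------------------------------------------------------------

def build_daily_feature_set(days: list, seed: int = 0) -> dict:
    """Assemble the 32 home parameters (plus ``n_valid_days``) for one
    subject from per-day event records."""
    valid = filter_valid_days(days)
    feats: dict[str, float] = {}

    # per-day walking percent, overall and per class
    for cls in ("ALL",) + BOUT_CLASSES:
        per_day = [daily_walking_percent(d, cls) for d in valid]
        key = f"Gait_{cls}"
        feats[f"{key}_min"], feats[f"{key}_avg"], feats[f"{key}_max"] = \
            min_avg_max_over_days(per_day)

    # pooled per-second speed distributions
    pools = {cls: [] for cls in ("ALL",) + BOUT_CLASSES}
    for d in valid:
        for b in d.bouts:
            pools["ALL"].append(b.per_second_speed)
            pools[classify_bout(b)].append(b.per_second_speed)
    for cls in ("ALL",) + BOUT_CLASSES:
        if pools[cls]:
            pooled = np.concatenate(pools[cls])
            p50, p95 = pooled_distribution_stats(pooled)
        else:
            p50 = p95 = float("nan")
        feats[f"V_{cls}_P50"], feats[f"V_{cls}_P95"] = p50, p95

    fit = fit_bimodal_modes(np.concatenate(pools["ALL"]) if pools["ALL"] else [],
                            seed=seed)
    feats["V_mu1"], feats["V_mu2"] = fit.v_mu1, fit.v_mu2

    # sit-to-stands and turns
    powers = np.concatenate([[t.peak_power for t in d.sit_to_stands] for d in valid]
                            or [[]])
    omegas = np.concatenate([[t.peak_omega for t in d.turns] for d in valid] or [[]])
    feats["P_H_P50"], feats["P_H_P95"] = (
        pooled_distribution_stats(powers) if powers.size else (float("nan"),) * 2)
    feats["omega_H_P50"], feats["omega_H_P95"] = (
        pooled_distribution_stats(omegas) if omegas.size else (float("nan"),) * 2)
    for key, cat in (("SiSt", "sit_to_stand"), ("Turns", "turn")):
        rates = [events_per_hour(d, cat) for d in valid]
        feats[f"{key}_min"], feats[f"{key}_avg"], feats[f"{key}_max"] = \
            min_avg_max_over_days(rates)

    feats["n_valid_days"] = len(valid)
    _assert_invariants(feats)
    return feats


def _assert_invariants(feats: dict) -> None:
    for key in ("Gait_ALL", "Gait_SWB", "Gait_MWB", "Gait_LWB", "SiSt", "Turns"):
        lo, av, hi = feats[f"{key}_min"], feats[f"{key}_avg"], feats[f"{key}_max"]
        if not (lo <= av + 1e-12 and av <= hi + 1e-12):
            raise ValueError(f"min<=avg<=max violated for {key}")
    for key in ("V_ALL", "V_SWB", "V_MWB", "V_LWB", "P_H", "omega_H"):
        p50, p95 = feats[f"{key}_P50"], feats[f"{key}_P95"]
        if not (np.isnan(p50) or p50 <= p95 + 1e-12):
            raise ValueError(f"P50<=P95 violated for {key}")
    if not feats["V_mu1"] <= feats["V_mu2"]:
        raise ValueError("V_mu1 must not exceed V_mu2")
    for key in feats:
        if key.startswith("Gait_") and not np.isnan(feats[key]):
            if not -1e-9 <= feats[key] <= 100.0 + 1e-9:
                raise ValueError(f"{key} outside [0, 100] percent")
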